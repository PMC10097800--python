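"""Discretized stress fields and scalar-stress kinematics.

A :class:`StressField` holds, for one operating point, the finite-volume
cell volumes [m^3] and the effective scalar stress per cell [Pa], together
with the flow rate [m^3/s].  Fields usually arrive with precomputed
stresses (mirroring a solver export of volumes and equivalent stresses);
raw velocity-gradient / dissipation records are an optional input path via
:func:`effective_stress`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CellKinematics",
    "StressField",
    "strain_rate_tensor",
    "scalar_equivalent_stress",
    "effective_stress",
    "poiseuille_field",
]


@dataclass(frozen=True)
class CellKinematics:
    """Per-cell kinematic inputs for the effective-stress reduction.

    Either ``grad_u`` (a 3x3 velocity-gradient tensor, [1/s]) or the
    time-averaged contraction ``sij_sq_mean`` (S_ij*S_ij, [1/s^2]) must be
    supplied; ``eps_mod`` is the modeled turbulent dissipation rate
    [m^2/s^3].
    """

    mu: float
    rho: float
    eps_mod: float = 0.0
    grad_u: Optional[np.ndarray] = None
    sij_sq_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError("mu must be > 0")
        if not (self.rho > 0):
            raise ValueError("rho must be > 0")
        if self.eps_mod < 0:
            raise ValueError("eps_mod must be >= 0")
        if self.sij_sq_mean is not None and self.sij_sq_mean < 0:
            raise ValueError("sij_sq_mean must be >= 0")
        if self.grad_u is None and self.sij_sq_mean is None:
            raise ValueError("either grad_u or sij_sq_mean is required")


@dataclass
class StressField:
    """Cell volumes and effective stresses for one operating point."""

    cell_volumes: np.ndarray
    tau_eff: np.ndarray
    Q: float
    label: str = ""

    def __post_init__(self) -> None:
        self.cell_volumes = np.asarray(self.cell_volumes, dtype=float)
        self.tau_eff = np.asarray(self.tau_eff, dtype=float)
        if self.cell_volumes.ndim != 1 or self.tau_eff.ndim != 1:
            raise ValueError("cell_volumes and tau_eff must be 1-D")
        if self.cell_volumes.size != self.tau_eff.size:
            raise ValueError(
                f"length mismatch: {self.cell_volumes.size} volumes vs "
                f"{self.tau_eff.size} stresses"
            )
        if self.cell_volumes.size < 1:
            raise ValueError("field must contain at least one cell")
        if not np.all(np.isfinite(self.cell_volumes)) or not np.all(
            np.isfinite(self.tau_eff)
        ):
            raise ValueError("non-finite values in field")
        if np.any(self.cell_volumes <= 0):
            raise ValueError("all cell volumes must be > 0")
        if np.any(self.tau_eff < 0):
            raise ValueError("all stresses must be >= 0")
        if not (self.Q > 0):
            raise ValueError("flow rate Q must be > 0")
        self._log_cache: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def n_cells(self) -> int:
        return int(self.cell_volumes.size)

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.cell_volumes))

    def log_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(ln tau, ln dV) restricted to cells with tau > 0, cached.

        Zero-stress cells contribute nothing to the hemolysis integral for
        alpha > 0 and are dropped up front.
        """
        if self._log_cache is None:
            pos = self.tau_eff > 0
            self._log_cache = (
                np.log(self.tau_eff[pos]),
                np.log(self.cell_volumes[pos]),
            )
        return self._log_cache


def strain_rate_tensor(grad_u: np.ndarray) -> np.ndarray:
    """Symmetric part of the velocity gradient: S = (G + G^T)/2."""
    g = np.asarray(grad_u, dtype=float)
    if g.shape != (3, 3):
        raise ValueError(f"grad_u must be 3x3, got shape {g.shape}")
    return 0.5 * (g + g.T)


def scalar_equivalent_stress(S: np.ndarray, mu: float) -> float:
    """Scalar stress from the second invariant: tau_s = mu*sqrt(2*S_ij*S_ij)."""
    s = np.asarray(S, dtype=float)
    if s.shape != (3, 3):
        raise ValueError(f"S must be 3x3, got shape {s.shape}")
    return float(mu * math.sqrt(2.0 * float(np.sum(s * s))))


def effective_stress(kin: CellKinematics) -> float:
    """Effective stress including the modeled turbulent contribution.

    tau_eff = sqrt(2*mu^2*mean(S_ij S_ij) + rho*mu*eps_mod); the laminar
    limit (eps_mod = 0) recovers :func:`scalar_equivalent_stress` on the
    mean field.
    """
    if kin.sij_sq_mean is not None:
        sij_sq = float(kin.sij_sq_mean)
    else:
        S = strain_rate_tensor(kin.grad_u)
        sij_sq = float(np.sum(S * S))
    return math.sqrt(2.0 * kin.mu**2 * sij_sq + kin.rho * kin.mu * kin.eps_mod)


def poiseuille_field(
    R: float,
    L: float,
    Q: float,
    mu: float,
    n_radial: int,
    label: str = "poiseuille",
) -> StressField:
    """Analytic laminar pipe-flow stress field on annular cells.

    The wall shear stress is ``tau_w = 4*mu*Q/(pi*R^3)`` and the profile is
    linear in radius, ``tau(r) = tau_w * r/R``.  Cell k sits at radius
    ``r_k = (k + 1/2)*dr`` with exact annular volume; the volumes sum to
    ``pi*R^2*L`` by construction.
    """
    if not (R > 0 and L > 0 and Q > 0 and mu > 0):
        raise ValueError("R, L, Q and mu must all be > 0")
    if n_radial < 1:
        raise ValueError("n_radial must be >= 1")

    dr = R / n_radial
    edges = np.linspace(0.0, R, n_radial + 1)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    volumes = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * L
    tau_w = 4.0 * mu * Q / (math.pi * R**3)
    tau = tau_w * r_mid / R
    return StressField(cell_volumes=volumes, tau_eff=tau, Q=Q, label=label)
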