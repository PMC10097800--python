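"""Power-law hemolysis model and MIH conversions.

The central quantity is the hemolysis value ``H``, the ratio of released
(plasma-free) to total hemoglobin.  A stress-based power law couples an
equivalent scalar stress ``tau`` [Pa] and an exposure time ``t`` [s]::

    H = C * tau**alpha * t**beta

All arithmetic that raises stresses or the prefactor ``C`` to powers is done
in the log domain: well-performing constant sets reach ``C ~ 1e-30`` and
``alpha ~ 20``, for which the naive expression under/overflows in float64.

Units are SI throughout (Pa, s, m^3, m^3/s).  Flow rates given in l/min are
converted at the boundary with ``1 l/min = 1/60000 m^3/s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "ConstantSet",
    "ExperimentalMIHInputs",
    "LMIN_TO_M3S",
    "builtin_constant_sets",
    "get_constant_set",
    "load_constant_sets",
    "power_law_H",
    "linearize",
    "delinearize_to_mih",
    "mih_experimental",
]

#: 1 l/min expressed in m^3/s.
LMIN_TO_M3S = 1.0 / 60000.0

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ConstantSet:
    """One (C, alpha, beta) power-law constant triple.

    ``C`` carries units Pa^-alpha * s^-beta so that ``H`` is dimensionless;
    ``alpha`` and ``beta`` are dimensionless exponents.
    """

    name: str
    C: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ValueError(f"constant set {self.name!r}: C must be > 0, got {self.C}")
        if not (self.alpha > 0):
            raise ValueError(
                f"constant set {self.name!r}: alpha must be > 0, got {self.alpha}"
            )
        if not (self.beta > 0):
            raise ValueError(
                f"constant set {self.name!r}: beta must be > 0, got {self.beta}"
            )

    @property
    def ln_C(self) -> float:
        return math.log(self.C)

    def as_position(self) -> np.ndarray:
        """Return the (ln C, alpha, beta) search-space coordinates."""
        return np.array([self.ln_C, self.alpha, self.beta], dtype=float)

    @classmethod
    def from_position(cls, position: Iterable[float], name: str = "particle") -> "ConstantSet":
        """Build a set from (ln C, alpha, beta) coordinates."""
        ln_c, alpha, beta = (float(v) for v in position)
        return cls(name=name, C=math.exp(ln_c), alpha=alpha, beta=beta)


@dataclass(frozen=True)
class ExperimentalMIHInputs:
    """Measured quantities entering the experimental MIH formula.

    delta_fHb : increase of plasma-free hemoglobin [mg/dl]
    Hb        : total blood hemoglobin concentration [mg/dl]
    delta_t   : total circuit time [s]
    V         : circuit blood volume [m^3]
    Q         : flow rate [m^3/s]
    Hct       : hematocrit, volume fraction in [0, 1)
    """

    delta_fHb: float
    Hb: float
    delta_t: float
    V: float
    Q: float
    Hct: float

    def __post_init__(self) -> None:
        if self.delta_fHb < 0:
            raise ValueError("delta_fHb must be >= 0")
        for attr in ("Hb", "delta_t", "V", "Q"):
            if not (getattr(self, attr) > 0):
                raise ValueError(f"{attr} must be > 0")
        if not (0.0 <= self.Hct < 1.0):
            raise ValueError(f"Hct must be in [0, 1), got {self.Hct}")


# Published constant sets.  The first four stem from laminar validation
# experiments; FT-M / FT-L are swarm-optimized sets (FT-M is numerically
# extreme and only usable through log-domain evaluation).
_BUILTIN = (
    ConstantSet("GW", 3.62e-7, 2.416, 0.785),
    ConstantSet("HO", 1.8e-8, 1.991, 0.765),
    ConstantSet("ZT", 1.228e-7, 1.9918, 0.6606),
    ConstantSet("FZ", 1.745e-8, 1.963, 0.7762),
    ConstantSet("FT-M", 4.256e-24, 10.2860, 2.8073),
    ConstantSet("FT-L", 1.000e-9, 1.8277, 0.5392),
)


def builtin_constant_sets() -> list[ConstantSet]:
    """Return the registry of named constant sets (GW, HO, ZT, FZ, FT-M, FT-L)."""
    return list(_BUILTIN)


def get_constant_set(name: str) -> ConstantSet:
    """Look a built-in constant set up by name (case-insensitive)."""
    for k in _BUILTIN:
        if k.name.lower() == name.lower():
            return k
    known = ", ".join(k.name for k in _BUILTIN)
    raise KeyError(f"unknown constant set {name!r}; known sets: {known}")


def load_constant_sets(path) -> list[ConstantSet]:
    """Load constant sets from a YAML file.

    The file holds a list of mappings with keys ``name``, ``C``, ``alpha``,
    ``beta``.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a list of constant-set mappings")
    sets = []
    for i, entry in enumerate(raw):
        try:
            sets.append(
                ConstantSet(
                    name=str(entry["name"]),
                    C=float(entry["C"]),
                    alpha=float(entry["alpha"]),
                    beta=float(entry["beta"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed constant set at index {i}") from exc
    return sets


def power_law_H(tau: ArrayLike, t: ArrayLike, k: ConstantSet) -> ArrayLike:
    """Hemolysis value H = C * tau**alpha * t**beta.

    Evaluated as ``exp(ln C + alpha*ln tau + beta*ln t)`` so extreme constant
    sets stay representable.  ``tau == 0`` or ``t == 0`` yields exactly 0.
    Accepts scalars or arrays (broadcasting applies).
    """
    tau_arr = np.asarray(tau, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")

    tau_b, t_b = np.broadcast_arrays(tau_arr, t_arr)
    out = np.zeros(tau_b.shape, dtype=float)
    pos = (tau_b > 0) & (t_b > 0)
    if np.any(pos):
        ln_h = k.ln_C + k.alpha * np.log(tau_b[pos]) + k.beta * np.log(t_b[pos])
        out[pos] = np.exp(ln_h)
    if np.isscalar(tau) and np.isscalar(t):
        return float(out)
    return out


def linearize(H: ArrayLike, beta: float) -> ArrayLike:
    """Linearized hemolysis value H_L = H**(1/beta)."""
    if not (beta > 0):
        raise ValueError(f"beta must be > 0, got {beta}")
    h = np.asarray(H, dtype=float)
    if np.any(h < 0):
        raise ValueError("H must be >= 0")
    out = np.zeros(h.shape, dtype=float)
    pos = h > 0
    out[pos] = np.exp(np.log(h[pos]) / beta)
    return float(out) if np.isscalar(H) else out


def delinearize_to_mih(H_L: ArrayLike, beta: float) -> ArrayLike:
    """MIH = H_L**beta * 1e6."""
    if not (beta > 0):
        raise ValueError(f"beta must be > 0, got {beta}")
    hl = np.asarray(H_L, dtype=float)
    if np.any(hl < 0):
        raise ValueError("H_L must be >= 0")
    out = np.zeros(hl.shape, dtype=float)
    pos = hl > 0
    out[pos] = np.exp(beta * np.log(hl[pos]) + math.log(1e6))
    return float(out) if np.isscalar(H_L) else out


def mih_experimental(x: ExperimentalMIHInputs) -> float:
    """Experimental MIH from circuit measurements.

    MIH_exp = (delta_fHb / Hb) * (V / (delta_t * Q)) * (1 - Hct) * 1e6
    """
    return (
        (x.delta_fHb / x.Hb)
        * (x.V / (x.delta_t * x.Q))
        * (1.0 - x.Hct)
        * 1e6
    )
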