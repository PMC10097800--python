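"""Synthetic stress fields and experiments with known ground truth.

Device flows carry strongly right-skewed stress distributions spanning
roughly 0.1-1000 Pa, which the lognormal generator emulates; the analytic
Poiseuille field (in :mod:`hemoswarm.stressfield`) covers the laminar-tube
limit.  :func:`gen_experiment` closes the parameter-recovery loop: records
generated noise-free from a constant set are matched exactly by that set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hemoswarm.hemomodels import ConstantSet
from hemoswarm.mihcalc import mih_volume_integral
from hemoswarm.fitness import OperatingPointRecord
from hemoswarm.stressfield import StressField, poiseuille_field

__all__ = [
    "SyntheticStudySpec",
    "gen_lognormal_field",
    "gen_experiment",
    "scale_field_to_target",
    "blasius_friction",
    "relative_deviation",
]


@dataclass
class SyntheticStudySpec:
    """Recipe for a synthetic optimization study.

    ``field_specs`` is a list of mappings, each with a ``kind`` key
    (``"lognormal"`` or ``"poiseuille"``) plus that generator's keyword
    arguments (excluding the seed, which is derived from ``seed``).
    """

    true_constants: ConstantSet
    field_specs: Sequence[dict]
    uncertainty_fraction: float = 0.1
    noise_sd_log: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.uncertainty_fraction < 0:
            raise ValueError("uncertainty_fraction must be >= 0")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if not self.field_specs:
            raise ValueError("field_specs must be non-empty")


def gen_lognormal_field(
    n_cells: int,
    mu_log_tau: float,
    sd_log_tau: float,
    total_volume: float,
    Q: float,
    seed: Optional[int] = None,
    label: str = "lognormal",
) -> StressField:
    """Right-skewed stress field: ln(tau) ~ Normal(mu, sd^2), equal volumes."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sd_log_tau < 0:
        raise ValueError("sd_log_tau must be >= 0")
    if not (total_volume > 0 and Q > 0):
        raise ValueError("total_volume and Q must be > 0")
    rng = np.random.default_rng(seed)
    tau = np.exp(rng.normal(mu_log_tau, sd_log_tau, size=n_cells))
    volumes = np.full(n_cells, total_volume / n_cells)
    return StressField(cell_volumes=volumes, tau_eff=tau, Q=Q, label=label)


def _build_field(spec: dict, seed: Optional[int], index: int) -> StressField:
    kind = spec.get("kind")
    kwargs = {k: v for k, v in spec.items() if k != "kind"}
    kwargs.setdefault("label", f"synth-{index}")
    if kind == "lognormal":
        kwargs.setdefault("seed", None if seed is None else seed + index)
        return gen_lognormal_field(**kwargs)
    if kind == "poiseuille":
        return poiseuille_field(**kwargs)
    raise ValueError(f"unknown field kind {kind!r}")


def gen_experiment(spec: SyntheticStudySpec) -> list[OperatingPointRecord]:
    """Synthetic operating-point records with known ground truth.

    Each record's central MIH is the true-constants volume-integral value
    on its field, optionally perturbed by multiplicative lognormal noise;
    the uncertainty band is ``+/- uncertainty_fraction * MIH_exp``.
    """
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 10_000)
    records = []
    for i, fs in enumerate(spec.field_specs):
        f = _build_field(fs, spec.seed, i)
        mih_true = mih_volume_integral(f, spec.true_constants)
        if mih_true <= 0:
            raise ValueError(f"field {f.label!r} yields zero MIH under the truth")
        noise = rng.normal(0.0, spec.noise_sd_log) if spec.noise_sd_log > 0 else 0.0
        mih_exp = mih_true * math.exp(noise)
        records.append(
            OperatingPointRecord(
                label=f.label,
                mih_exp=mih_exp,
                mih_unc=spec.uncertainty_fraction * mih_exp,
                field=f,
                group="synthetic",
            )
        )
    return records


def scale_field_to_target(
    field: StressField, k: ConstantSet, mih_target: float
) -> StressField:
    """Rescale stresses so the field yields exactly ``mih_target`` under ``k``.

    Uses the homogeneity MIH(f*tau) = f**alpha * MIH(tau): the factor is
    f = (target/current)**(1/alpha), computed in the log domain.
    """
    if not (mih_target > 0):
        raise ValueError("mih_target must be > 0")
    mih_current = mih_volume_integral(field, k)
    if mih_current == 0.0:
        raise ValueError("cannot scale an all-zero stress field")
    f = math.exp((math.log(mih_target) - math.log(mih_current)) / k.alpha)
    return StressField(
        cell_volumes=field.cell_volumes.copy(),
        tau_eff=field.tau_eff * f,
        Q=field.Q,
        label=field.label,
    )


def blasius_friction(Re: float) -> float:
    """Turbulent pipe friction factor lambda = 0.316 / Re**0.25."""
    if not (Re > 0):
        raise ValueError(f"Re must be > 0, got {Re}")
    return 0.316 / Re**0.25


def relative_deviation(sim_value: float, exp_value: float) -> float:
    """Signed percent deviation 100*(sim - exp)/exp."""
    if exp_value == 0:
        raise ValueError("exp_value must be nonzero")
    return 100.0 * (sim_value - exp_value) / exp_value
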