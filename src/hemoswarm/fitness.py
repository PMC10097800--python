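"""Optimization objectives: dead-band mean error and modified correlation.

Per operating point the error is

    xi = 0                                   if MIH_num lies within the
                                             experimental uncertainty band
    xi = | 1/(|ln(MIH_num/MIH_exp)| + 1) - 1 |   otherwise

so xi grows from 0 toward 1 as the prediction drifts decades away from the
measurement, reaching 1 in the limits MIH_num -> 0 and MIH_num -> inf.  The
band check is inclusive at both bounds and the log-ratio always uses the
central experimental value.  Negative lower bounds are clamped to zero, so
any prediction below the upper bound is in-bounds for such records.

The second objective is r = |Pearson(A, B) - 1| on the raw MIH values, 0
for a perfect positive correlation and 2 for a perfect anticorrelation.
The overall scalar ranking fitness is F_n = (eta + r)/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from hemoswarm.hemomodels import ConstantSet
from hemoswarm.mihcalc import _ln_mih_from_logs, ln_mih_volume_integral
from hemoswarm.stressfield import StressField

__all__ = [
    "OperatingPointRecord",
    "FitnessReport",
    "xi_error",
    "mean_error",
    "modified_correlation",
    "overall_fitness",
    "evaluate_fitness",
    "make_objective",
]


@dataclass
class OperatingPointRecord:
    """Experimental hemolysis at one operating point.

    ``field`` may be ``None`` for records whose stress fields are not
    available (published fixtures); such records can only be used where no
    numerical MIH is required.
    """

    label: str
    mih_exp: float
    mih_unc: float
    field: Optional[StressField] = None
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.mih_exp > 0):
            raise ValueError(f"record {self.label!r}: mih_exp must be > 0")
        if self.mih_unc < 0:
            raise ValueError(f"record {self.label!r}: mih_unc must be >= 0")

    @property
    def mih_exp_min(self) -> float:
        return max(0.0, self.mih_exp - self.mih_unc)

    @property
    def mih_exp_max(self) -> float:
        return self.mih_exp + self.mih_unc


@dataclass
class FitnessReport:
    """Full fitness diagnostics of one constant set against the records."""

    constants: ConstantSet
    mih_num: np.ndarray
    xi: np.ndarray
    eta: float
    r_mod: float
    F_n: float
    NiB: int
    R_subsets: dict = field(default_factory=dict)


def _xi_from_ln(ln_mih: float, rec: OperatingPointRecord) -> float:
    """Dead-band error from ln(MIH_num); handles the MIH=0 limit exactly."""
    lo, hi = rec.mih_exp_min, rec.mih_exp_max
    if ln_mih == -math.inf:
        # zero prediction: in-bounds only if the clamped lower bound is 0
        # *and* 0 is an admissible value -- the band is defined on MIH >= lo,
        # and lo == 0 admits it; otherwise the limit value is 1.
        if lo == 0.0:
            return 0.0
        return 1.0
    ln_lo = -math.inf if lo == 0.0 else math.log(lo)
    ln_hi = math.log(hi)
    if ln_lo <= ln_mih <= ln_hi:
        return 0.0
    abs_ln_ratio = abs(ln_mih - math.log(rec.mih_exp))
    return abs(1.0 / (abs_ln_ratio + 1.0) - 1.0)


def xi_error(mih_num: float, rec: OperatingPointRecord) -> float:
    """Bounded per-operating-point error in [0, 1)."""
    if mih_num < 0:
        raise ValueError(f"mih_num must be >= 0, got {mih_num}")
    ln_mih = -math.inf if mih_num == 0.0 else math.log(mih_num)
    return _xi_from_ln(ln_mih, rec)


def mean_error(xi_values: Sequence[float]) -> float:
    """Arithmetic mean of the per-point errors."""
    xi = np.asarray(xi_values, dtype=float)
    if xi.size == 0:
        raise ValueError("xi_values must be non-empty")
    return float(np.mean(xi))


def modified_correlation(A: Sequence[float], B: Sequence[float]) -> float:
    """r = |Pearson(A, B) - 1|, in [0, 2].

    Degenerate samples (zero variance in either input, or fewer than two
    points after pairing) return the worst value 2 with a warning so an
    optimizer embedding this objective can keep moving.
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.size != b.size:
        raise ValueError("A and B must have equal lengths")
    if a.size < 2:
        raise ValueError("need at least two sample points")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        warnings.warn("degenerate sample (zero variance); returning r = 2")
        return 2.0
    # Pearson is invariant under positive rescaling; normalize so samples
    # spanning hundreds of log-decades do not overflow the moment sums.
    a = a / np.max(np.abs(a))
    b = b / np.max(np.abs(b))
    rho = stats.pearsonr(a, b).statistic
    return float(abs(rho - 1.0))


def overall_fitness(eta: float, r: float) -> float:
    """Scalar ranking fitness F_n = (eta + r)/2; 0 is a perfect match."""
    if eta < 0 or r < 0:
        raise ValueError("eta and r must be >= 0")
    return 0.5 * (eta + r)


def _pearson_plain(a: np.ndarray, b: np.ndarray) -> float:
    """Unmodified Pearson coefficient; NaN for degenerate samples."""
    if a.size < 2 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    a = a / np.max(np.abs(a))
    b = b / np.max(np.abs(b))
    return float(stats.pearsonr(a, b).statistic)


def evaluate_fitness(
    sets: Sequence[ConstantSet], records: Sequence[OperatingPointRecord]
) -> list[FitnessReport]:
    """Full fitness report per constant set over the operating points.

    Every record must reference a resolvable stress field.  Besides the two
    objectives this also reports NiB (number of points inside their
    uncertainty bands) and per-group unmodified Pearson coefficients.
    """
    if not sets or not records:
        raise ValueError("sets and records must be non-empty")
    for rec in records:
        if rec.field is None:
            raise ValueError(f"record {rec.label!r} has no stress field attached")

    mih_exp = np.array([rec.mih_exp for rec in records])
    groups = [rec.group for rec in records]

    reports = []
    for k in sets:
        ln_mih = np.array([ln_mih_volume_integral(rec.field, k) for rec in records])
        mih_num = np.where(np.isneginf(ln_mih), 0.0, np.exp(ln_mih))
        xi = np.array(
            [_xi_from_ln(lm, rec) for lm, rec in zip(ln_mih, records)]
        )
        eta = mean_error(xi)
        if len(records) >= 2:
            r_mod = modified_correlation(mih_num, mih_exp)
        else:
            warnings.warn("single record: correlation degenerate; r = 2")
            r_mod = 2.0
        nib = int(np.sum(xi == 0.0))
        r_subsets = {"all": _pearson_plain(mih_num, mih_exp)}
        for g in sorted(set(groups)):
            if not g:
                continue
            sel = np.array([gi == g for gi in groups])
            r_subsets[g] = _pearson_plain(mih_num[sel], mih_exp[sel])
        reports.append(
            FitnessReport(
                constants=k,
                mih_num=mih_num,
                xi=xi,
                eta=eta,
                r_mod=r_mod,
                F_n=overall_fitness(eta, r_mod),
                NiB=nib,
                R_subsets=r_subsets,
            )
        )
    return reports


def make_objective(
    records: Sequence[OperatingPointRecord],
) -> Callable[[np.ndarray], tuple[float, float]]:
    """Build the (eta, r) objective over (ln C, alpha, beta) positions.

    This is the optimizer's hot path: per-record log arrays are extracted
    once, and each call costs one log-sum-exp per record.  All intermediate
    hemolysis values are kept in the log domain until needed, so positions
    anywhere in the wide optimization domain produce finite objectives.
    """
    if len(records) < 2:
        raise ValueError("need at least two operating points")
    pre = []
    for rec in records:
        if rec.field is None:
            raise ValueError(f"record {rec.label!r} has no stress field attached")
        ln_tau, ln_vol = rec.field.log_arrays()
        pre.append((ln_tau, ln_vol, math.log(rec.field.Q), rec))
    mih_exp = np.array([rec.mih_exp for rec in records])

    def objective(position: np.ndarray) -> tuple[float, float]:
        ln_c, alpha, beta = (float(v) for v in position)
        ln_mih = np.empty(len(pre))
        xi = np.empty(len(pre))
        for i, (ln_tau, ln_vol, ln_q, rec) in enumerate(pre):
            lm = _ln_mih_from_logs(ln_tau, ln_vol, ln_q, ln_c, alpha, beta)
            ln_mih[i] = lm
            xi[i] = _xi_from_ln(lm, rec)
        eta = float(np.mean(xi))
        # exponentiate relative to the largest log value; Pearson is
        # invariant under this positive rescaling and it cannot overflow.
        m = np.max(ln_mih)
        if m == -math.inf:
            return eta, 2.0
        mih_scaled = np.exp(ln_mih - m)
        if np.ptp(mih_scaled) == 0.0 or np.ptp(mih_exp) == 0.0:
            return eta, 2.0
        rho = _pearson_plain(mih_scaled, mih_exp)
        return eta, float(abs(rho - 1.0))

    return objective
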