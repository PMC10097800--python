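"""Principal-component line fitting in (ln C, alpha, beta) space.

Near-optimal power-law constant sets do not cluster at a point: they align
along a line in (ln C, alpha, beta).  :func:`fit_line` extracts that line
from good archive particles by PCA; :func:`analytic_solution_line` gives
the exact line for the two-uniform-operating-point toy problem, where the
zero-error set of each operating point is a plane

    ln C + alpha*ln(tau) + beta*ln(t_res) = ln(MIH_target * 1e-6)

and the solution line is the intersection of the two planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["Line3D", "fit_line", "point_line_distance", "analytic_solution_line"]


def _apply_sign_convention(direction: np.ndarray) -> np.ndarray:
    """Resolve the PCA sign ambiguity.

    Convention: the ln C component is made negative (matching the published
    orientation of the optimal-constant line); if it is zero, the first
    nonzero component is made positive.
    """
    d = np.asarray(direction, dtype=float)
    if d[0] != 0.0:
        return -d if d[0] > 0 else d
    for comp in d:
        if comp != 0.0:
            return d if comp > 0 else -d
    raise ValueError("zero direction vector")


@dataclass(frozen=True)
class Line3D:
    """A line ``point(s) = centroid + s * direction`` in (ln C, alpha, beta)."""

    centroid: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if c.shape != (3,) or d.shape != (3,):
            raise ValueError("centroid and direction must be 3-vectors")
        norm = float(np.linalg.norm(d))
        if norm == 0.0:
            raise ValueError("direction must be nonzero")
        d = _apply_sign_convention(d / norm)
        object.__setattr__(self, "centroid", c)
        object.__setattr__(self, "direction", d)

    def point_at(self, s: float) -> np.ndarray:
        return self.centroid + s * self.direction


def fit_line(
    points: Sequence[Sequence[float]],
    fitness: Optional[Sequence[float]] = None,
    threshold: Optional[float] = 0.5,
) -> Line3D:
    """Leading principal axis of the (optionally fitness-filtered) cloud.

    When ``fitness`` is given, only points with F_n strictly below
    ``threshold`` enter the fit (unweighted).  At least two points must
    survive.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if fitness is not None and threshold is not None:
        fn = np.asarray(fitness, dtype=float)
        if fn.size != pts.shape[0]:
            raise ValueError("fitness length must match number of points")
        pts = pts[fn < threshold]
    if pts.shape[0] < 2:
        raise ValueError(
            f"need at least 2 points below the threshold, got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # leading right singular vector == leading covariance eigenvector
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return Line3D(centroid=centroid, direction=vt[0])


def point_line_distance(point: Sequence[float], line: Line3D) -> float:
    """Euclidean distance of a point to the line."""
    p = np.asarray(point, dtype=float)
    delta = p - line.centroid
    along = float(np.dot(delta, line.direction))
    return float(np.linalg.norm(delta - along * line.direction))


def analytic_solution_line(
    op1: tuple[float, float, float], op2: tuple[float, float, float]
) -> Line3D:
    """Exact solution line for two uniform-stress operating points.

    Each operating point is ``(tau, t_res, mih_target)`` with uniform
    stress tau [Pa], residence time t_res [s] and target MIH.  The returned
    line is the intersection of the two zero-error planes; its direction is
    the normalized cross product of the plane normals
    ``(1, ln tau, ln t_res)``.
    """
    rows = []
    rhs = []
    for tau, t_res, mih in (op1, op2):
        if not (tau > 0 and t_res > 0 and mih > 0):
            raise ValueError("tau, t_res and mih_target must all be > 0")
        rows.append([1.0, math.log(tau), math.log(t_res)])
        rhs.append(math.log(mih * 1e-6))
    n1, n2 = (np.array(r) for r in rows)
    direction = np.cross(n1, n2)
    norm = float(np.linalg.norm(direction))
    if norm < 1e-12 * float(np.linalg.norm(n1) * np.linalg.norm(n2)):
        raise ValueError("degenerate operating points: zero-error planes are parallel")
    # particular point: minimum-norm solution of the two plane equations
    A = np.vstack([n1, n2])
    point, *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
    return Line3D(centroid=point, direction=direction)
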