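"""Sampling of reference vertex degree plot (rVDP) pairs.

A reference vertex degree plot is a nondecreasing integer array of length
``N`` with entries in ``[1, N-1]``; a digraph has one for indegrees (``D-``)
and one for outdegrees (``D+``), and the two must share the same sum ``D``
(the number of edges).  The sampler draws a pair of clamped straight lines
over the ``N x N`` square with matched areas under them, rounds each line to
an integer plot, and repairs any residual sum mismatch with random unit
adjustments.

The shape of each line is controlled by an angle ``alpha ~ U(0, pi/2)`` and
an intercept ``beta``: the first line's intercept is a uniform shift of the
line along one of the square's sides (direction chosen by a fair coin), and
the second line's intercept is solved by bisection so the areas - and hence,
approximately, the degree sums - agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Margin keeping sampled angles away from {0, pi/2}, where tan degenerates.
ANGLE_EPS = 1e-9

#: Default bisection tolerance on the matched area, in squared vertex units
#: (half a unit cell).
AREA_TOL = 0.5

_BISECTION_MAX_ITER = 200


@dataclass(frozen=True)
class LineSpec:
    """A clamped straight line ``y(x) = x tan(alpha) + beta`` over ``[0, N]``.

    ``alpha`` is the steepness angle in radians, strictly inside
    ``(0, pi/2)``; ``beta`` the intercept in vertex-degree units, allowed in
    ``[-N tan(alpha), N]`` (the bisection search interval).
    """

    alpha: float
    beta: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < math.pi / 2:
            raise ValueError(f"alpha must lie in (0, pi/2), got {self.alpha}")
        slope = math.tan(self.alpha)
        if not -self.n * slope <= self.beta <= self.n:
            raise ValueError(
                f"beta={self.beta} outside [-N tan(alpha), N] = "
                f"[{-self.n * slope}, {self.n}]"
            )

    @property
    def slope(self) -> float:
        return math.tan(self.alpha)

    def __call__(self, x: float) -> float:
        return x * self.slope + self.beta


@dataclass(frozen=True)
class ReferencePlotPair:
    """A matched pair of sorted integer degree plots with equal sums.

    ``d_minus`` holds the target indegrees and ``d_plus`` the target
    outdegrees, both sorted ascending with entries in ``[1, N-1]``.
    """

    n: int
    d_minus: np.ndarray
    d_plus: np.ndarray

    def __post_init__(self) -> None:
        dm = np.asarray(self.d_minus, dtype=np.int64)
        dp = np.asarray(self.d_plus, dtype=np.int64)
        object.__setattr__(self, "d_minus", dm)
        object.__setattr__(self, "d_plus", dp)
        if dm.shape != (self.n,) or dp.shape != (self.n,):
            raise ValueError("degree arrays must have length N")
        for name, arr in (("d_minus", dm), ("d_plus", dp)):
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be nondecreasing")
            if arr.size and (arr.min() < 1 or arr.max() > self.n - 1):
                raise ValueError(f"{name} entries must lie in [1, N-1]")
        if int(dm.sum()) != int(dp.sum()):
            raise ValueError("degree sums must be equal")

    @property
    def total_degree(self) -> int:
        """The common degree sum ``D`` = number of edges of a realizing graph."""
        return int(self.d_minus.sum())

    @property
    def density(self) -> float:
        """``D / (N(N-1))``: the density any exact realization would have."""
        return self.total_degree / (self.n * (self.n - 1))


def clamped_line_area(line: LineSpec) -> float:
    """Area under ``clamp(y(x), 0, N)`` over ``[0, N]``, computed analytically.

    The clamped line has at most two breakpoints (where it crosses ``y = 0``
    and ``y = N``); the integral is a sum of a triangle/trapezoid and a
    rectangle.  The result lies in ``[0, N**2]``.
    """
    n = line.n
    slope = line.slope
    # Crossing abscissae of y=0 and y=N (x0 < x1 since slope > 0).
    x0 = -line.beta / slope
    x1 = (n - line.beta) / slope
    a = min(max(x0, 0.0), float(n))
    b = min(max(x1, 0.0), float(n))
    ya = min(max(line(a), 0.0), float(n))
    yb = min(max(line(b), 0.0), float(n))
    area = 0.5 * (ya + yb) * (b - a) + float(n) * (n - b)
    return float(min(max(area, 0.0), float(n) ** 2))


def solve_beta2(
    alpha2: float,
    target_area: float,
    n: int,
    tol: float = AREA_TOL,
    max_iter: int = _BISECTION_MAX_ITER,
) -> float:
    """Find the intercept giving a prescribed clamped area at angle ``alpha2``.

    The area is nondecreasing in the intercept, ranging from 0 at
    ``-N tan(alpha2)`` to ``N**2`` at ``N``, so bisection over that interval
    converges.  Returns ``beta2`` with
    ``|clamped_line_area(alpha2, beta2) - target_area| <= tol``.
    """
    if not 0.0 <= target_area <= float(n) ** 2:
        raise ValueError(f"target area {target_area} outside [0, N^2]")
    slope = math.tan(alpha2)
    lo, hi = -n * slope, float(n)
    beta = 0.5 * (lo + hi)
    for _ in range(max_iter):
        beta = 0.5 * (lo + hi)
        area = clamped_line_area(LineSpec(alpha2, beta, n))
        if abs(area - target_area) <= tol:
            return beta
        if area < target_area:
            lo = beta
        else:
            hi = beta
    return beta


def discretize(line: LineSpec) -> np.ndarray:
    """Round a clamped line to an integer degree plot.

    Entry ``i`` (1-based abscissa) is ``floor(max(min(y(i) + 0.5, N-1), 1))``,
    i.e. round-half-up with both ends clamped into ``[1, N-1]``.  The output
    is nondecreasing because the line is.
    """
    n = line.n
    x = np.arange(1, n + 1, dtype=np.float64)
    y = x * line.slope + line.beta
    return np.floor(np.maximum(np.minimum(y + 0.5, n - 1), 1.0)).astype(np.int64)


def balance(
    d_minus: np.ndarray, d_plus: np.ndarray, rng: np.random.Generator
) -> ReferencePlotPair:
    """Equalize the sums of two degree plots by random unit adjustments.

    While the sums differ, a random index ``k`` and one of two moves are
    drawn equiprobably: increment an entry of the deficit-side array (if it
    stays ``<= N-1``) or decrement an entry of the surplus-side array (if it
    stays ``>= 1``).  A draw whose move would violate its bound is discarded
    and redrawn.  Each applied move shrinks the gap by one, and an applicable
    move always exists while the gap is nonzero, so the loop terminates.

    Unit adjustments at interior indices can break sortedness, so both
    arrays are re-sorted before the pair is returned (reference plots are
    defined as sorted arrays).  Equal-sum inputs are returned unchanged.
    """
    dm = np.asarray(d_minus, dtype=np.int64).copy()
    dp = np.asarray(d_plus, dtype=np.int64).copy()
    if dm.shape != dp.shape or dm.ndim != 1:
        raise ValueError("degree arrays must be 1-D and of equal length")
    n = dm.size
    gap = int(dm.sum()) - int(dp.sum())
    if gap == 0:
        return ReferencePlotPair(n, dm, dp)
    # (surplus, deficit) view: moves either decrement surplus or increment deficit.
    surplus, deficit = (dm, dp) if gap > 0 else (dp, dm)
    remaining = abs(gap)
    ks = moves = np.empty(0)
    cursor = 0
    while remaining > 0:
        if cursor >= ks.size:
            chunk = max(64, 2 * remaining)
            ks = rng.integers(0, n, size=chunk)
            moves = rng.integers(0, 2, size=chunk)
            cursor = 0
        k, move = ks[cursor], moves[cursor]
        cursor += 1
        if move == 0:
            if deficit[k] + 1 <= n - 1:
                deficit[k] += 1
                remaining -= 1
        else:
            if surplus[k] - 1 >= 1:
                surplus[k] -= 1
                remaining -= 1
    dm.sort()
    dp.sort()
    return ReferencePlotPair(n, dm, dp)


def sample_line_pair(
    n: int, rng: np.random.Generator, tol: float = AREA_TOL
) -> tuple[LineSpec, LineSpec]:
    """Draw the two reference lines with matched clamped areas.

    The first line gets a uniform angle and a uniform shift ``delta`` along
    one of the two sides of the square adjacent to the origin (direction
    chosen by a fair coin): shifting up gives ``beta1 = delta``, shifting
    right gives ``beta1 = -delta * tan(alpha1)``.  The second line gets an
    independent uniform angle and its intercept is solved so the areas match.
    """
    if n < 2:
        raise ValueError(f"need at least 2 vertices, got {n}")
    alpha1 = rng.uniform(ANGLE_EPS, math.pi / 2 - ANGLE_EPS)
    delta = rng.uniform(0.0, float(n))
    if rng.integers(0, 2) == 0:
        beta1 = delta
    else:
        beta1 = -delta * math.tan(alpha1)
    line1 = LineSpec(alpha1, beta1, n)
    alpha2 = rng.uniform(ANGLE_EPS, math.pi / 2 - ANGLE_EPS)
    beta2 = solve_beta2(alpha2, clamped_line_area(line1), n, tol=tol)
    return line1, LineSpec(alpha2, beta2, n)


def generate_rvdp(
    n: int, rng: np.random.Generator, tol: float = AREA_TOL
) -> ReferencePlotPair:
    """Sample a reference degree-plot pair for a digraph on ``n`` vertices.

    Orchestrates the full procedure: draw two equal-area clamped lines,
    round both to integer plots, assign them to the in- and out-sides by a
    fair coin, and repair the rounding-induced sum mismatch with
    :func:`balance`.  Output satisfies all :class:`ReferencePlotPair`
    invariants.
    """
    if n < 2:
        raise ValueError(f"need at least 2 vertices, got {n}")
    line1, line2 = sample_line_pair(n, rng, tol=tol)
    plot1, plot2 = discretize(line1), discretize(line2)
    if rng.integers(0, 2) == 0:
        d_minus, d_plus = plot1, plot2
    else:
        d_minus, d_plus = plot2, plot1
    return balance(d_minus, d_plus, rng)
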