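"""Feller run-theory model for treatment-interruption risk.

A patient's daily dosing is modelled as a sequence of independent Bernoulli
trials: each day the dose is taken with probability ``q`` (the average
adherence) and missed with probability ``p = 1 - q``.  A treatment
interruption is a run of at least ``r`` consecutive missed days.  The
probability that at least one such run occurs within an ``n``-day window is
approximated by Feller's classical run-length formula

    Prob(TI) ~= 1 - (1 - p*x) / ((r + 1 - r*x) * q) * x**-(n + 1)

where ``x`` is the smallest root >= 1 of the characteristic polynomial

    f(x) = 1 - x + q * p**r * x**(r + 1).

The approximation is extremely accurate over the adherence range of clinical
interest (see :mod:`tirisk.exact_oracle` for the exact dynamic-programming
counterpart used to validate it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RunModelParams",
    "FellerRoot",
    "RiskPoint",
    "AdherenceInterval",
    "DEFAULT_INTERVALS",
    "round_half_up",
    "solve_feller_root",
    "interruption_probability",
    "risk_curve",
    "expected_frequencies",
    "expected_cohort_counts",
    "find_cutpoint_adherence",
]


class RootConvergenceError(RuntimeError):
    """The characteristic polynomial bracket failed to change sign."""


@dataclass(frozen=True)
class RunModelParams:
    """Parameter bundle (q, r, n) of the run model.

    q : probability of taking the dose on any given day (average adherence)
    r : interruption length in days (run length), integer >= 1
    n : observation window in days, integer >= r
    """

    q: float
    r: int
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if int(self.r) != self.r or self.r < 1:
            raise ValueError(f"r must be an integer >= 1, got {self.r}")
        if int(self.n) != self.n or self.n < self.r:
            raise ValueError(f"n must be an integer >= r, got {self.n}")
        object.__setattr__(self, "r", int(self.r))
        object.__setattr__(self, "n", int(self.n))

    @property
    def p(self) -> float:
        """Probability of missing the dose on any given day, 1 - q."""
        return 1.0 - self.q


@dataclass(frozen=True)
class FellerRoot:
    """Smallest root >= 1 of 1 - x + q*p^r*x^(r+1) = 0."""

    x: float
    residual: float
    iterations: int


@dataclass(frozen=True)
class RiskPoint:
    """Predicted interruption probability at a given average adherence."""

    q: float
    prob_ti: float
    clamped: bool = False


@dataclass(frozen=True)
class AdherenceInterval:
    """Half-open adherence interval [lower, upper)."""

    lower: float
    upper: float
    midpoint: float = field(default=None)  # type: ignore[assignment]
    label: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValueError(
                f"need 0 <= lower < upper <= 1, got [{self.lower}, {self.upper})"
            )
        if self.midpoint is None:
            object.__setattr__(self, "midpoint", (self.lower + self.upper) / 2.0)
        if self.label is None:
            object.__setattr__(self, "label", f"{self.lower:g}-<{self.upper:g}")

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


#: The ten adherence intervals used to bin the observed cohort: wide bins at
#: low adherence where observations are sparse, narrowing toward the top of
#: the scale where the (negatively skewed) adherence distribution
#: concentrates.
DEFAULT_INTERVALS: tuple[AdherenceInterval, ...] = tuple(
    AdherenceInterval(lo, hi)
    for lo, hi in [
        (0.40, 0.50),
        (0.50, 0.60),
        (0.60, 0.65),
        (0.65, 0.70),
        (0.70, 0.75),
        (0.75, 0.80),
        (0.80, 0.85),
        (0.85, 0.90),
        (0.90, 0.934),
        (0.934, 0.967),
    ]
)


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention used in risk tables)."""
    quantum = Decimal(1).scaleb(-decimals)
    result = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(result)


def _characteristic(x: float, q: float, p: float, r: int) -> float:
    return 1.0 - x + q * p**r * x ** (r + 1)


def solve_feller_root(params: RunModelParams) -> FellerRoot:
    """Locate the smallest root x >= 1 of the characteristic polynomial.

    The polynomial f(x) = 1 - x + q*p^r*x^(r+1) satisfies f(1) = q*p^r > 0
    for 0 < q < 1 and decreases until its stationary point
    x_turn = ((r+1)*q*p^r)^(-1/r); the relevant root is bracketed by
    [1, x_turn].  Brent's method on that bracket is followed by a Newton
    polish so the residual is at machine precision.

    Raises
    ------
    ValueError
        If q is 0 or 1 (callers must use the closed-form limits).
    RootConvergenceError
        If the bracket does not change sign (degenerate double-root case,
        e.g. r = 1 with q = p = 0.5).
    """
    q, p, r = params.q, params.p, params.r
    if q <= 0.0 or q >= 1.0:
        raise ValueError("solve_feller_root requires 0 < q < 1")
    coeff = q * p**r
    x_turn = ((r + 1) * coeff) ** (-1.0 / r)
    f_turn = _characteristic(x_turn, q, p, r)
    # f_turn == 0 is the tangency (double-root) case, where the probability
    # formula's denominator vanishes: treat it as degenerate too
    if f_turn >= 0.0:
        raise RootConvergenceError(
            f"no sign change on [1, {x_turn:.6g}] for q={q}, r={r}: "
            "degenerate (double-root) regime"
        )
    x, info = brentq(
        _characteristic,
        1.0,
        x_turn,
        args=(q, p, r),
        xtol=1e-15,
        rtol=4 * np.finfo(float).eps,
        full_output=True,
    )
    iterations = info.iterations
    # Newton polish: f'(x) = -1 + (r+1)*q*p^r*x^r
    for _ in range(3):
        fx = _characteristic(x, q, p, r)
        if abs(fx) <= 1e-15:
            break
        dfx = -1.0 + (r + 1) * coeff * x**r
        if dfx == 0.0:
            break
        step = fx / dfx
        if 1.0 <= x - step <= x_turn:
            x -= step
            iterations += 1
    return FellerRoot(x=x, residual=_characteristic(x, q, p, r), iterations=iterations)


def interruption_probability(params: RunModelParams) -> RiskPoint:
    """Feller-approximate probability of >= 1 miss-run of length >= r in n days.

    Closed-form limits: q = 1 gives probability 0 (no misses possible);
    q = 0 gives probability 1 whenever n >= r.  Results marginally outside
    [0, 1] (the approximation can stray at the extremes) are clamped, and
    the clamping is flagged on the returned :class:`RiskPoint`.
    """
    q, p, r, n = params.q, params.p, params.r, params.n
    if q >= 1.0:
        return RiskPoint(q=q, prob_ti=0.0)
    if q <= 0.0:
        return RiskPoint(q=q, prob_ti=1.0)
    root = solve_feller_root(params)
    x = root.x
    prob_no_run = (1.0 - p * x) / ((r + 1.0 - r * x) * q) * x ** -(n + 1)
    prob = 1.0 - prob_no_run
    clamped = prob < 0.0 or prob > 1.0
    return RiskPoint(q=q, prob_ti=min(1.0, max(0.0, prob)), clamped=clamped)


def risk_curve(
    q_grid: Sequence[float], r: int, n: int, *, check_monotone: bool = True
) -> list[RiskPoint]:
    """Evaluate the interruption probability over an ascending adherence grid.

    The predicted risk is non-increasing in adherence; this is asserted on
    the output as a guard against solver pathologies.
    """
    grid = list(q_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("q_grid must be sorted ascending")
    points = [interruption_probability(RunModelParams(q=q, r=r, n=n)) for q in grid]
    if check_monotone:
        probs = [pt.prob_ti for pt in points]
        if any(b > a + 1e-12 for a, b in zip(probs, probs[1:])):
            raise AssertionError("risk curve is not non-increasing in q")
    return points


def expected_frequencies(
    intervals: Iterable[AdherenceInterval],
    r: int,
    n: int,
    per: int = 100,
) -> list[dict]:
    """Expected interruption counts per ``per`` persons for each interval.

    The interval midpoint supplies the model's q input; the expected count
    is round-half-up(per * prob).
    """
    if per <= 0:
        raise ValueError("per must be positive")
    rows = []
    for interval in intervals:
        point = interruption_probability(RunModelParams(q=interval.midpoint, r=r, n=n))
        rows.append(
            {
                "label": interval.label,
                "lower": interval.lower,
                "upper": interval.upper,
                "midpoint": interval.midpoint,
                "prob": point.prob_ti,
                "expected": int(round_half_up(per * point.prob_ti)),
            }
        )
    return rows


def expected_cohort_counts(
    binned,
    r: int,
    n: int,
    *,
    rounding: str = "paper",
) -> list[dict]:
    """Expected interrupted-participant counts for a binned cohort.

    ``binned`` is anything exposing ``intervals`` and per-interval
    participant counts ``n_i`` (e.g. :class:`tirisk.eam_processing.BinnedCohort`),
    or an iterable of (interval, count) pairs.

    rounding='paper' rounds the predicted probability to two decimals before
    multiplying by the interval headcount, then rounds half-up — the
    convention required to reproduce published two-stage risk tables.
    rounding='exact' multiplies the unrounded probability.
    """
    if rounding not in ("paper", "exact"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if hasattr(binned, "intervals"):
        pairs = list(zip(binned.intervals, binned.n_i))
    else:
        pairs = list(binned)
    rows = []
    for interval, count in pairs:
        point = interruption_probability(RunModelParams(q=interval.midpoint, r=r, n=n))
        prob = point.prob_ti
        if rounding == "paper":
            prob = round_half_up(prob, 2)
        rows.append(
            {
                "label": interval.label,
                "midpoint": interval.midpoint,
                "n": int(count),
                "prob": prob,
                "expected": int(round_half_up(prob * count)),
            }
        )
    return rows


def find_cutpoint_adherence(
    target_prob: float, r: int, n: int, *, tol: float = 1e-8
) -> float:
    """Invert the risk curve: the adherence q* at which Prob(TI) = target.

    Exploits monotonicity of the interruption probability in q.  The search
    bracket is the combinatorial always/never band: below the forced-run
    bound every arrangement of doses contains a run (probability 1), above
    the run-free bound none can (probability 0).
    """
    from .exact_oracle import guaranteed_bounds

    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must lie strictly inside (0, 1)")
    bounds = guaranteed_bounds(r, n)
    lo = max(bounds.forced_max_adherence, 1e-9)
    hi = min(bounds.impossible_min_adherence, 1.0 - 1e-12)

    def objective(q: float) -> float:
        return interruption_probability(RunModelParams(q=q, r=r, n=n)).prob_ti - target_prob

    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo < 0.0 or f_hi > 0.0:
        raise ValueError(
            f"target probability {target_prob} not achievable on "
            f"adherence bracket [{lo:.4g}, {hi:.4g}]"
        )
    q_star = brentq(objective, lo, hi, xtol=tol / 10)
    if abs(objective(q_star)) > tol:
        raise RootConvergenceError("cut-point inversion did not reach tolerance")
    return q_star
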