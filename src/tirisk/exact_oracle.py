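"""Exact and simulation ground truth for miss-run probabilities.

Three independent routes to the probability that an i.i.d. Bernoulli
day-series of length n contains a run of at least r consecutive misses:

* a trailing-run Markov-chain dynamic programme (exact, any n),
* exhaustive enumeration of all 2^n day-sequences (exact, small n),
* seeded Monte-Carlo simulation.

Also provides the pigeonhole always/never adherence bounds: with d dose-days
out of n, a miss-run >= r is *forced* for every arrangement when the n - d
misses cannot be broken into d + 1 gaps of length <= r - 1, and *impossible*
for every arrangement when n - d <= r - 1.  These bounds justify excluding
extreme adherence values from any model test: their outcome carries no
information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.stats import binomtest

__all__ = [
    "RunStateVector",
    "exact_run_probability",
    "exact_run_states",
    "brute_force_run_probability",
    "simulate_run_outcomes",
    "guaranteed_bounds",
    "GuaranteedBounds",
    "has_run",
]

_BRUTE_FORCE_MAX_N = 22


@dataclass
class RunStateVector:
    """Distribution over trailing-miss-run lengths 0..r-1 plus absorption.

    ``state_probs[j]`` is the probability the current trailing run of misses
    has length j, conditional jointly on no run of length r having occurred;
    ``absorbed`` is the probability a run >= r has already occurred.  The
    entries and ``absorbed`` sum to 1.
    """

    state_probs: np.ndarray
    absorbed: float

    def total(self) -> float:
        return float(self.state_probs.sum() + self.absorbed)


def exact_run_states(q: float, r: int, n: int) -> RunStateVector:
    """Run the trailing-run DP for n steps and return the final state.

    Each day: a miss (probability p) extends the trailing run by one, a
    taken dose (probability q) resets it to zero, and a run reaching length
    r is absorbed permanently.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if r < 1 or n < 0:
        raise ValueError("need r >= 1 and n >= 0")
    p = 1.0 - q
    state = np.zeros(r)
    state[0] = 1.0
    absorbed = 0.0
    for _ in range(n):
        new = np.empty(r)
        new[0] = state.sum() * q
        new[1:] = state[:-1] * p
        absorbed += state[-1] * p
        state = new
    return RunStateVector(state_probs=state, absorbed=absorbed)


def exact_run_probability(q: float, r: int, n: int) -> float:
    """Exact P(at least one miss-run of length >= r in n i.i.d. days)."""
    return exact_run_states(q, r, n).absorbed


def has_run(misses: np.ndarray, r: int) -> np.ndarray:
    """Row-wise: does each binary miss-sequence contain a run of r ones?"""
    misses = np.atleast_2d(np.asarray(misses, dtype=np.int64))
    n = misses.shape[1]
    if r > n:
        return np.zeros(misses.shape[0], dtype=bool)
    out = np.zeros(misses.shape[0], dtype=bool)
    # running count of trailing consecutive misses
    trail = np.zeros(misses.shape[0], dtype=np.int64)
    for j in range(n):
        trail = (trail + 1) * misses[:, j]
        out |= trail >= r
    return out


@lru_cache(maxsize=64)
def _run_counts_by_misses(r: int, n: int) -> np.ndarray:
    """count[m] = number of n-bit sequences with m misses containing a run >= r."""
    seqs = np.arange(2**n, dtype=np.uint32)
    bits = (seqs[:, None] >> np.arange(n, dtype=np.uint32)) & 1
    miss_count = bits.sum(axis=1)
    contains = has_run(bits, r)
    counts = np.zeros(n + 1, dtype=np.int64)
    np.add.at(counts, miss_count[contains], 1)
    return counts


def brute_force_run_probability(q: float, r: int, n: int) -> float:
    """Exact run probability by exhaustive enumeration of all 2^n sequences.

    Each sequence is weighted q^(#taken) * p^(#missed).  Refuses n > 22
    (cost guard); intended purely as an independent oracle.
    """
    if n > _BRUTE_FORCE_MAX_N:
        raise ValueError(f"brute force limited to n <= {_BRUTE_FORCE_MAX_N}")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    p = 1.0 - q
    counts = _run_counts_by_misses(r, n)
    m = np.arange(n + 1)
    return float(np.sum(counts * p**m * q ** (n - m)))


def simulate_run_outcomes(
    q: float, r: int, n: int, reps: int = 50_000, seed: int = 42
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo estimate of the run probability with an exact 95% CI.

    Simulates ``reps`` i.i.d. Bernoulli day-series with a generator seeded
    by ``seed`` and reports the fraction containing a miss-run >= r,
    together with the Clopper-Pearson interval for that fraction.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    misses = rng.random((reps, n)) >= q
    hits = int(has_run(misses.astype(np.int64), r).sum())
    estimate = hits / reps
    ci = binomtest(hits, reps).proportion_ci(confidence_level=0.95, method="exact")
    return estimate, (ci.low, ci.high)


class GuaranteedBounds(NamedTuple):
    forced_max_dose_days: int
    impossible_min_dose_days: int
    forced_max_adherence: float
    impossible_min_adherence: float


def guaranteed_bounds(r: int, n: int) -> GuaranteedBounds:
    """Pigeonhole bounds on dose-day counts for forced/impossible runs.

    With d dose-days, the n - d misses split into at most d + 1 gaps; if
    n - d > (r - 1)(d + 1) some gap must reach length r regardless of the
    arrangement, i.e. a run is forced for d <= ceil((n - r + 1)/r) - 1.
    Conversely no arrangement can contain a run when n - d <= r - 1, i.e.
    d >= n - r + 1.  Both thresholds are also returned as adherence
    fractions d/n.
    """
    if r < 1 or n < r:
        raise ValueError("need r >= 1 and n >= r")
    d_forced = math.ceil((n - r + 1) / r) - 1
    d_impossible = n - r + 1
    return GuaranteedBounds(
        forced_max_dose_days=d_forced,
        impossible_min_dose_days=d_impossible,
        forced_max_adherence=d_forced / n,
        impossible_min_adherence=d_impossible / n,
    )
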