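"""Model-evaluation battery for the interruption-risk model.

Covers the full validation protocol for an a-priori (parameter-free) risk
model against an observed cohort: per-interval exact binomial goodness of
fit, fixed cut-point classification with Clopper-Pearson intervals, the
Brier score, rank-based AUROC with a Hanley-McNeil confidence interval,
k-fold cross-validated AUROC, and an exhaustive max-accuracy cut-point
scan.

Because the risk model has no fitted parameters, "training" folds in the
cross-validation carry no information; the procedure reduces to fold-wise
AUROC estimation and is implemented (and documented) as such.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import binom, norm, rankdata

from .model_core import AdherenceInterval, RunModelParams, interruption_probability

__all__ = [
    "GofResult",
    "ProportionEstimate",
    "ClassificationReport",
    "binomial_gof_test",
    "clopper_pearson_ci",
    "classify_at_cutpoint",
    "brier_score",
    "auroc",
    "kfold_cv_auroc",
    "max_accuracy_cutpoint",
    "gof_by_interval",
    "evaluate_cohort",
]


@dataclass
class GofResult:
    interval: AdherenceInterval
    predicted: float
    observed_k: int
    n: int
    p_value: float


@dataclass
class ProportionEstimate:
    value: float
    lower: float
    upper: float


@dataclass
class ClassificationReport:
    cutpoint: float
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    accuracy: ProportionEstimate
    brier: float | None = None
    auroc: ProportionEstimate | None = None
    cv_auroc: ProportionEstimate | None = None
    max_accuracy: float | None = None
    max_accuracy_cutpoint: float | None = None
    confusion: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def binomial_gof_test(
    observed_k: int, n: int, predicted_prob: float, method: str = "minlike"
) -> float:
    """Two-sided exact binomial goodness-of-fit p-value.

    method='minlike' (default) sums P(X = j) over every j whose point
    probability does not exceed that of the observed count — the two-siding
    convention of the classical exact binomial test.  method='central'
    doubles the smaller tail.  Degenerate null probabilities 0 and 1 are
    handled exactly.
    """
    if not 0 <= observed_k <= n:
        raise ValueError("need 0 <= observed_k <= n")
    if not 0.0 <= predicted_prob <= 1.0:
        raise ValueError("predicted_prob must lie in [0, 1]")
    if predicted_prob == 0.0:
        return 1.0 if observed_k == 0 else 0.0
    if predicted_prob == 1.0:
        return 1.0 if observed_k == n else 0.0
    ks = np.arange(n + 1)
    pmf = binom.pmf(ks, n, predicted_prob)
    p_obs = pmf[observed_k]
    if method == "minlike":
        # tolerance guards against ties broken by floating-point noise
        p = pmf[pmf <= p_obs * (1 + 1e-10)].sum()
    elif method == "central":
        lower = pmf[: observed_k + 1].sum()
        upper = pmf[observed_k:].sum()
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(1.0, p))


def clopper_pearson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    lower = Beta(alpha/2; k, n-k+1), upper = Beta(1-alpha/2; k+1, n-k);
    the lower limit is 0 at k = 0 and the upper limit 1 at k = n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _proportion(k: int, n: int, alpha: float = 0.05) -> ProportionEstimate:
    lo, hi = clopper_pearson_ci(k, n, alpha)
    return ProportionEstimate(value=k / n, lower=lo, upper=hi)


def classify_at_cutpoint(
    predictions: Sequence[float],
    outcomes: Sequence[int],
    cutpoint: float = 0.50,
) -> ClassificationReport:
    """Sensitivity, specificity and accuracy at a fixed probability cut point.

    Predicted positive iff predicted probability >= cutpoint (boundary
    inclusive).  Each statistic carries a Clopper-Pearson 95% interval.
    """
    probs = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if probs.shape != y.shape:
        raise ValueError("predictions and outcomes must align")
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class")
    pred_pos = probs >= cutpoint
    tp = int(np.sum(pred_pos & (y == 1)))
    fn = int(np.sum(~pred_pos & (y == 1)))
    tn = int(np.sum(~pred_pos & (y == 0)))
    fp = int(np.sum(pred_pos & (y == 0)))
    return ClassificationReport(
        cutpoint=cutpoint,
        sensitivity=_proportion(tp, tp + fn),
        specificity=_proportion(tn, tn + fp),
        accuracy=_proportion(tp + tn, y.size),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


def brier_score(predictions: Sequence[float], outcomes: Sequence[int]) -> float:
    """Mean squared difference between predicted probabilities and outcomes.

    0 for a perfect 0/1 predictor; exactly 0.25 for the non-informative
    constant-0.5 predictor regardless of the outcome vector.
    """
    probs = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if probs.shape != y.shape:
        raise ValueError("predictions and outcomes must align")
    return float(np.mean((probs - y) ** 2))


def auroc(
    predictions: Sequence[float], outcomes: Sequence[int], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Rank-based (Mann-Whitney) AUROC with ties credited one half.

    The confidence interval uses the Hanley-McNeil variance approximation;
    limits are clipped to [0, 1].
    """
    probs = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(probs)
    area = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    a = float(area)
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a**2)
        + (n_neg - 1) * (q2 - a**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(norm.ppf(1 - alpha / 2))
    return a, (max(0.0, a - z * se), min(1.0, a + z * se))


def kfold_cv_auroc(
    predictions: Sequence[float],
    outcomes: Sequence[int],
    k: int = 10,
    seed: int = 42,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], int]:
    """Fold-wise AUROC of a fixed a-priori model.

    Participants are randomly split (seeded) into k near-equal folds and
    the AUROC evaluated on each hold-out fold.  The model has no fitted
    parameters, so the training folds carry no information beyond
    mirroring the usual cross-validation protocol.  Single-class folds are
    skipped and counted; an error is raised if more than half the folds
    are unusable.

    Returns (fold-mean AUROC, normal-approximation CI, n_skipped_folds).
    """
    probs = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if probs.size < k:
        raise ValueError("need at least k observations")
    rng = np.random.default_rng(seed)
    order = rng.permutation(probs.size)
    folds = np.array_split(order, k)
    areas = []
    skipped = 0
    for fold in folds:
        yf = y[fold]
        if yf.min() == yf.max():
            skipped += 1
            continue
        areas.append(auroc(probs[fold], yf)[0])
    if skipped > k / 2:
        raise ValueError(f"{skipped} of {k} folds are single-class")
    areas_arr = np.asarray(areas)
    mean = float(areas_arr.mean())
    se = float(areas_arr.std(ddof=1) / np.sqrt(areas_arr.size)) if areas_arr.size > 1 else 0.0
    z = float(norm.ppf(1 - alpha / 2))
    return mean, (max(0.0, mean - z * se), min(1.0, mean + z * se)), skipped


def max_accuracy_cutpoint(
    scores: Sequence[float],
    outcomes: Sequence[int],
    positive_when: str = "high",
) -> tuple[float, float]:
    """Exhaustive scan for the score cut maximising classification accuracy.

    Candidate cuts are the observed score values.  positive_when='high'
    predicts positive for score >= cut (risk-probability scores);
    positive_when='low' predicts positive for score < cut (raw adherence,
    where low adherence means high risk).  Accuracy ties are broken toward
    the higher cut value.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class")
    best_cut, best_acc = None, -1.0
    for cut in np.unique(s):
        if positive_when == "high":
            pred = s >= cut
        elif positive_when == "low":
            pred = s < cut
        else:
            raise ValueError(f"unknown positive_when {positive_when!r}")
        acc = float(np.mean(pred == (y == 1)))
        if acc > best_acc or (acc == best_acc and cut > best_cut):
            best_cut, best_acc = float(cut), acc
    return best_cut, best_acc


def gof_by_interval(binned, r: int, n: int) -> list[GofResult]:
    """Exact binomial goodness of fit per adherence interval.

    For each interval the model probability at the midpoint is the null
    proportion; the observed interrupted count k_i out of n_i participants
    is tested two-sided.  Empty intervals are skipped.
    """
    results = []
    for interval, n_i, k_i in zip(binned.intervals, binned.n_i, binned.k_i):
        if n_i == 0:
            continue
        predicted = interruption_probability(
            RunModelParams(q=interval.midpoint, r=r, n=n)
        ).prob_ti
        results.append(
            GofResult(
                interval=interval,
                predicted=predicted,
                observed_k=k_i,
                n=n_i,
                p_value=binomial_gof_test(k_i, n_i, predicted),
            )
        )
    return results


def evaluate_cohort(
    summaries: Iterable,
    binned,
    r: int = 3,
    n: int = 90,
    cutpoint: float = 0.50,
    k: int = 10,
    seed: int = 42,
) -> dict:
    """Full evaluation report for a summarised cohort.

    ``summaries`` provide per-participant average adherence and interruption
    flags; model predictions are computed at each participant's adherence.
    Returns a JSON-serialisable dict with the goodness-of-fit table,
    fixed-cut classification, Brier score, AUROC, cross-validated AUROC and
    the max-accuracy cut-point (searched on the adherence scale).
    """
    summaries = list(summaries)
    probs = np.array(
        [
            interruption_probability(
                RunModelParams(q=s.average_adherence, r=r, n=n)
            ).prob_ti
            for s in summaries
        ]
    )
    y = np.array([int(s.interrupted) for s in summaries])
    adherence = np.array([s.average_adherence for s in summaries])

    report = classify_at_cutpoint(probs, y, cutpoint)
    report.brier = brier_score(probs, y)
    area, ci = auroc(probs, y)
    report.auroc = ProportionEstimate(value=area, lower=ci[0], upper=ci[1])
    cv_mean, cv_ci, skipped = kfold_cv_auroc(probs, y, k=k, seed=seed)
    report.cv_auroc = ProportionEstimate(value=cv_mean, lower=cv_ci[0], upper=cv_ci[1])
    cut_adh, acc = max_accuracy_cutpoint(adherence, y, positive_when="low")
    report.max_accuracy = acc
    report.max_accuracy_cutpoint = cut_adh

    gof = gof_by_interval(binned, r, n)
    return {
        "gof": [
            {
                "interval": g.interval.label,
                "predicted": g.predicted,
                "observed_k": g.observed_k,
                "n": g.n,
                "observed_prop": g.observed_k / g.n,
                "p_value": g.p_value,
            }
            for g in gof
        ],
        "classification": report.to_dict(),
        "brier": report.brier,
        "auroc": {"value": area, "ci": list(ci)},
        "cv_auroc": {"value": cv_mean, "ci": list(cv_ci), "skipped_folds": skipped},
        "max_accuracy": {"accuracy": acc, "adherence_cutpoint": cut_adh},
        "params": {"r": r, "n": n, "cutpoint": cutpoint, "k": k, "seed": seed},
    }
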