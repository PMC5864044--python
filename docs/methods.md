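# Methods

## Model

Daily dosing is a Bernoulli process: on each day the dose is taken with
probability `q` (estimated by average adherence: monitored bottle openings
divided by prescribed doses) and missed with probability `p = 1 − q`. A
treatment interruption of length `r` is a run of `r` consecutive missed
days; the default operating point is `r = 3`, `n = 90` (a gap of more than
72 hours during the first 90 days of therapy, the window where
interruptions are most consequential).

The probability of at least one such run in `n` days is evaluated with
Feller's run-length approximation

    P(no run) = (1 − p·x) / ((r + 1 − r·x)·q) · x^−(n+1),  Prob(TI) = 1 − P(no run)

with `x` the smallest root ≥ 1 of `f(x) = 1 − x + q·p^r·x^(r+1)`. The model
has no fitted parameters: it is an a-priori probability statement, so
"training" it on data is meaningless and external validation reduces to
comparing its predictions with observed cohort frequencies.

Assumptions worth keeping in mind: days are independent and identically
distributed given `q` (no weekend effects, no miss clustering), the patient
has uninterrupted access to medication, and a day is binary — for
twice-daily regimens a day with one of two doses still counts as taken.

## Numerical treatment

* **Root solving.** `f(1) = q·p^r > 0` and `f` decreases to its stationary
  point `x_turn = ((r+1)·q·p^r)^(−1/r)`, so the relevant root is bracketed
  by `[1, x_turn]`. Brent's method on that bracket (a bracketed method
  cannot jump to the polynomial's second, larger root) is followed by a
  Newton polish; the returned residual is ≤ 1e−12 and in practice at
  machine precision. `f(x_turn) ≥ 0` means the bracket never changes sign —
  the tangency/double-root regime (e.g. `r = 1`, `q = p = 0.5`), where the
  formula's denominator vanishes; this is reported as a degenerate-input
  error rather than silently returning the tangent root.
* **Edge cases.** `q = 1` → probability 0; `q = 0` → 1 for `n ≥ r`. The
  approximation can stray marginally outside `[0, 1]` at extremes, so
  results are clamped and the clamping flagged on the returned value.
* **Accuracy.** Against the exact trailing-run Markov-chain computation the
  approximation is within 0.01 for `q ∈ [0.10, 0.97]`, `r ∈ {2..5}`,
  `n ∈ {30..365}`, and within ~1e−13 on the operating range
  `q ∈ [0.40, 0.967)`, `r = 3`, `n = 90`. For `r = 1` it is exact
  (`1 − q^n`).
* **Rounding for risk tables.** Expected counts use round-half-up. The
  cohort-count table offers two modes: `paper` rounds the probability to
  two decimals *before* multiplying by the interval headcount (the
  convention that reproduces published two-stage tables, e.g.
  0.55 × 19 = 10.45 → 10), and `exact` multiplies the unrounded
  probability. The two differ only when the second decimal matters at the
  headcount scale.
* **Interval midpoints.** Binned predictions evaluate the model at the
  arithmetic interval midpoint, including the irregular top intervals
  (0.90–<0.934 → 0.917, 0.934–<0.967 → 0.9505).
* **Cut-point inversion.** The predicted probability is strictly decreasing
  in `q`, so the adherence at which it crosses a target (0.50 by default,
  the "inflection point" used as the a-priori classification cut) is found
  by bracketed root-finding between the combinatorial always/never
  adherence bounds, to 1e−8. Note the 0.50-crossing is what is implemented,
  not a second-derivative zero.

## Exact oracles

The trailing-run DP tracks the distribution over trailing-miss-run lengths
`0..r−1` plus an absorbing "run occurred" state; probability mass is
conserved to 1e−12 at every step. It was chosen over inclusion-exclusion
for numerical stability at `n = 365`. Exhaustive enumeration of all `2^n`
sequences (refused above `n = 22`) and seeded Monte-Carlo simulation
provide two further independent routes; the test suite requires
DP ≡ enumeration to 1e−12.

Pigeonhole bounds: with `d` dose-days in `n`, the `n − d` misses split
into at most `d + 1` gaps, so a run ≥ r is forced for every arrangement
iff `n − d > (r−1)(d+1)` (`d ≤ ⌈(n−r+1)/r⌉ − 1`; 29 dose-days for
`r = 3, n = 90`) and impossible iff `n − d ≤ r − 1` (`d ≥ 88`). These
justify excluding adherence below 0.333 and at or above 0.967 from model
testing — the outcome there is determined by counting, not probability.

## EAM processing

Day `i` spans `[start + i·24 h, start + (i+1)·24 h)` anchored at the
therapy-start clock time; timestamps are naive. A day is "taken" if at
least one opening falls in it. Average adherence is capped at 1 (curiosity
openings and pocket dosing can push the raw ratio above 1); cap events are
flagged. Two interruption rules are provided and reported side by side:
the day-run rule (longest run of fully-missed days ≥ r, matching the
model's discretisation — the default) and the timestamp rule (any gap
between consecutive openings, window edges included, above 72 h), because
a ">72 hours" criterion is literally a duration. On logs whose openings
sit at fixed daily clock times (e.g. 08:00/20:00) the two rules coincide;
with irregular timing they can differ near the boundary. Exclusion bands
(<0.333 always-interrupt, [0.333, 0.40) sparse, ≥0.967 never-interrupt)
are configurable, and excluded participants carry their reason rather than
disappearing.

## Evaluation battery

* **Goodness of fit.** Per-interval exact binomial test of the observed
  interrupted count against the midpoint prediction. The two-sided p-value
  uses the minimum-likelihood convention (sum of all point probabilities no
  larger than the observed one); a central (doubled-tail) variant is
  available behind a flag. The minimum-likelihood convention is the one
  consistent with published per-interval p-values reconstructed from the
  printed proportions.
* **Classification.** Predicted positive iff predicted probability ≥ 0.50
  (boundary inclusive). Sensitivity, specificity and accuracy carry exact
  Clopper-Pearson 95% intervals.
* **Brier score.** Mean squared distance between prediction and outcome;
  the constant-0.5 predictor scores exactly 0.25 — the non-informative
  reference.
* **AUROC.** Mann-Whitney rank statistic with ties credited one half; the
  confidence interval uses the Hanley-McNeil variance approximation (the
  method is swappable; no single convention is canonical).
* **Cross-validation.** Because the model has no fitted parameters, k-fold
  cross-validation cannot re-estimate anything on training folds; it is
  implemented — deliberately and visibly — as fold-wise AUROC estimation
  on seeded random folds, with single-class folds skipped and counted.
* **Max-accuracy cut.** Exhaustive scan over observed values, ties broken
  toward the higher cut; on the adherence scale the positive direction is
  "below the cut".

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, so
the whole pipeline is testable without any external data.

* **Adherence distribution.** Per-participant `q` is drawn from a
  Beta(2.45, 0.30) truncated to [0.40, 0.967) by inverse-CDF sampling.
  The shape parameters were fit once so the truncated distribution matches
  the cohort profile the model was tested against — mean ≈ 0.815, median
  ≈ 0.87, skewness ≈ −1.05 — and are not tuning knobs. Defaults: 185
  participants, 90 days, two doses/day.
* **Dosing behaviour.** `iid` mode takes each day independently with
  probability `q` (the model's premise). `markov` mode is a two-state
  chain with P(miss | miss) = persistence and P(miss | taken) chosen so the
  stationary miss rate stays `1 − q`, initialised from the stationary
  distribution: every day is still marginally Bernoulli(q) but misses
  cluster. This is the deliberate model violation — clustered misses at
  high adherence inflate interruption frequencies above the i.i.d.
  prediction, the qualitative pattern a run model cannot capture. It is a
  probe, not a claim about how any real cohort behaves.
* **Event logs.** Taken days emit the scheduled openings (08:00/20:00 by
  default) with uniform jitter below two hours, so collapsing the log back
  to days recovers the input series exactly; round-tripping is tested.
* **What passing tests show.** Self-consistency: data generated under the
  model's own assumptions reproduce its predicted interval frequencies
  within Monte-Carlo error, and the evaluation machinery returns the
  expected metrics on them. They do not show that real dosing behaviour is
  i.i.d. — real cohorts exhibit miss clustering, observer effects and
  monitoring gaps the generator's i.i.d. mode deliberately lacks.

One subtlety found during development and worth recording: grouping
simulated participants by *realised* adherence and comparing interval
frequencies against the model at the measured value carries a small
structural bias (conditional on the realised dose count, all arrangements
are equally likely, which is not the i.i.d. marginal — differences up to
~0.04 in the steep region). Self-consistency checks therefore group on the
latent drawn `q`, for which the per-participant expectation is exact; the
analysis pipeline itself still bins on measured adherence, which is all an
observer ever has.

## Known limitations

* The Feller formula is an approximation; outside `q ∈ [0.10, 0.97]` or
  for very short windows its error can exceed the documented bounds
  (degenerate parameter regions raise instead of returning nonsense).
* No imputation of monitoring gaps: device non-use is indistinguishable
  from non-adherence in an opening log.
* The model is day-binary; partial-day dosing in multi-dose regimens is
  out of scope.
* No recalibration of the model to observed cohorts is provided — the
  model is a fixed a-priori instrument, and refitting it would change its
  character.
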