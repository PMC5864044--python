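# tirisk

Run-theory risk model for short-term antiretroviral treatment
interruptions, with exact oracles, electronic-adherence-monitor (EAM) log
processing, a model-evaluation battery, and a synthetic cohort generator.

## The problem

Patients on antiretroviral therapy (ART) are at risk of *treatment
interruptions* — several consecutive days without a dose — which are
strongly associated with virologic rebound. Clinicians usually have only a
summary measure of adherence (openings of an electronic pill-bottle cap
divided by prescribed doses). `tirisk` maps that single number to the
probability of an interruption.

Model each day as an independent Bernoulli trial: the dose is taken with
probability *q* (the average adherence) and missed with probability
*p* = 1 − *q*. A treatment interruption is a run of at least *r*
consecutive missed days. The probability of at least one such run in an
*n*-day window is given by Feller's run-length approximation

```
Prob(TI) ≈ 1 − (1 − p·x) / ((r + 1 − r·x)·q) · x^−(n+1)
```

where *x* is the smallest root ≥ 1 of the characteristic polynomial
1 − *x* + *q·p^r·x^(r+1)* = 0. For the clinical operating point (*r* = 3,
*n* = 90 — a >72-hour gap in the first 90 days of therapy) the
approximation agrees with the exact Markov-chain computation to better
than 10⁻¹³ across the whole analysable adherence range.

The package also provides everything needed to test the model against a
cohort: exact dynamic-programming / enumeration / Monte-Carlo oracles,
pigeonhole bounds identifying adherence levels where an interruption is
combinatorially forced or impossible, per-interval exact binomial
goodness of fit, fixed-cut-point classification with Clopper-Pearson
intervals, Brier score, AUROC with k-fold cross-validation, and a
seeded synthetic EAM cohort generator (i.i.d. or serially-correlated
dosing behaviour).

## Worked example

```python
>>> from tirisk import RunModelParams, interruption_probability, find_cutpoint_adherence
>>> interruption_probability(RunModelParams(q=0.825, r=3, n=90)).prob_ti
0.327052727038155
>>> find_cutpoint_adherence(0.50, r=3, n=90)
0.7866076903354564
```

A patient taking 82.5% of doses has a 0.33 probability of at least one
3-day interruption within 90 days; the predicted probability crosses 0.50
at 0.79 adherence — the natural classification cut point. Raising
adherence from 0.74 to 0.84 drops the predicted risk from 0.70 to 0.26,
whereas the same improvement from 0.60 to 0.70 only moves it from 0.98 to
0.83: interventions pay off most near the curve's steep midsection.

The same numbers from the command line:

```sh
$ tirisk risk --q 0.825 --r 3 --n 90
0.33
$ tirisk table            # ten-interval risk table (CSV)
$ tirisk cutpoint --target 0.5
0.786608
```

End-to-end synthetic pipeline:

```sh
$ tirisk simulate --n-participants 185 --seed 42 --out cohort/
$ tirisk summarize --daily cohort/daily.csv --out summary.csv
$ tirisk evaluate --summary summary.csv --report report.json
```

`report.json` contains the per-interval goodness-of-fit table,
sensitivity/specificity/accuracy at the 0.50 cut with exact confidence
intervals, Brier score, AUROC and cross-validated AUROC.

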