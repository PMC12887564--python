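# Methods

This note documents the models, conventions and numerical choices behind
`edlockin`, and what its synthetic-data experiments do and do not show.

## Evaluation model

A visit is scored on the inclusive 10-minute grid `t = 0, 10, …, 180`
(19 points; the grid is configurable but step must divide horizon). The
snapshot at `t` aggregates exactly the events with `offset ≤ t` — a closed
boundary, so an observation landing on a grid point is available at that
point. The decision rule is a first-crossing stopping rule: the prediction
locks to "admit" at the earliest grid point whose probability **strictly
exceeds** 0.5; a probability of exactly 0.5 never locks. Ties are therefore
conservative (no admission call), matching a rule phrased as "exceeds 50%".
A never-locking trace is a predicted discharge with its decision time set
to the 180-minute horizon; this convention matters only for diagnostics,
since the headline time-saved statistic is computed over true positives,
which by definition locked.

Per-time-point metrics treat not-yet-locked visits at time `t` as
provisional negatives. Under this convention TP(t) and FP(t) are
non-decreasing, TP+TN+FP+FN = n at every `t`, recall is non-decreasing in
`t` (its denominator, the number of admitted visits, is fixed), and the
horizon counts coincide with the final per-visit decision classes.
Irreversibility also implies the end-of-horizon FP count is at least the FP
count of a hypothetical evaluator that judges only the final snapshot; the
test suite checks this empirically.

Minutes saved for a true positive is `clinician decision time − lock
time`; it can be negative if the model locked later than the clinician.
Time deltas of FP/TN/FN visits are computed but reported only as
diagnostics — the clinician time of a discharged visit measures a
different event (the discharge conversation), so mixing it into the
headline statistic would be incoherent.

## Classifier

The classifier is an XGBoost binary ensemble with
`colsample_bytree=0.7, gamma=0.0, learning_rate=0.1, max_depth=15,
min_child_weight=7`, histogram tree method, single thread (for bit-stable
results on any machine). The number of boosting rounds is capped at 200
with early stopping (patience 20, log-loss) on a 10% visit-level slice of
the training data; on the default synthetic cohorts it stops around 40–60
rounds. Training rows are *all* (visit × grid point) snapshots labelled
with the visit-level outcome, because the deployed model must score partial
information at every interval. All splits are at the visit level; row-level
splits would leak a visit's own later snapshots into training. Static
evaluation thresholds probabilities at 0.5 (strict), the same rule the
lock-in simulator applies per point. Feature importance is gain-based,
normalised to sum 1. Undefined metrics (zero denominators, single-class
AUROC) are flagged as `None`, never coerced to 0.

## Synthetic cohort generator

The generator defines the study conditions for every experiment in the
package. It emulates:

* **Prevalence** 0.394 admitted.
* **Marginal mixes** over age decade (18–27 … ≥88), ten presenting
  specialties, triage urgency (Unknown, U0–U5) and arrival period (night /
  morning / afternoon / evening), proportional to the subgroup sizes of a
  large (~47k visit) Dutch ED evaluation cohort. Joint structure is sampled
  independently per dimension — only the marginals are anchored, because
  only marginal counts are published.
* **Admission propensity**: each covariate level contributes
  `logit(share_level) − logit(0.394)` to a linear predictor, where
  `share_level` is that level's published admitted fraction (e.g. U0
  ≈ 0.97, ages ≥88 ≈ 0.60, ages 18–27 ≈ 0.16); the intercept is solved by
  root-finding per cohort so the expected admitted fraction equals the
  configured prevalence exactly. Additive combination overstates the
  spread of the true joint propensity slightly; this is acceptable for an
  evaluation-pipeline testbed and keeps the generator identifiable from
  published marginals.
* **Clinician decision times**: two-parameter gamma per outcome. The
  admitted-outcome parameters (shape ≈ 2.15, scale ≈ 70.5) are solved by
  least squares in log-quantile space against quartiles (75, 131, 201) min;
  the discharged-outcome parameters (shape ≈ 3.20, scale ≈ 57.7) are solved
  so the 0.394-prevalence mixture matches (95, 151, 228) min. A gamma is
  used rather than a log-normal because the target quartiles are *less*
  log-skewed than any log-normal allows (131 > √(75·201) ≈ 122.8): the
  best log-normal puts the admitted median at 125.5 and Q3 at 205, while
  the gamma lands at (75.5, 128.8, 203.0) and the mixture at
  (94.7, 151.9, 227.3). Both solvers run at configuration time (cached) so
  changing the target quartiles re-calibrates automatically.
* **Event streams**: per-category homogeneous Poisson processes over the
  first 240 minutes, with a deterministic triage-assignment event at t=0.
  Categories mirror the order families that dominate ED admission
  prediction — inflammation, kidney function, blood count, blood culture,
  plus a vitals stream. Rates multiply by `exp(±shift·signal/2)` for
  admitted/discharged visits and event values shift similarly, so with
  `signal_strength > 0` cumulative features become more informative as the
  stay progresses (AUROC rises from ≈0.74 at t=0, statics only, to ≈0.92
  at t=180 on default cohorts), and with `signal_strength = 0` the event
  stream is pure noise. Event offsets are uniform over the window; events
  past the 180-minute horizon are kept in the table but never enter a
  snapshot.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: bed occupancy/queueing feedback, correlated
covariates (a 90-year-old surgical U4 visit is as likely as the marginals
allow), non-stationary arrival or order rates, repeat visits, informative
missingness, free-text/imaging information, and any coupling between
decision times and the event stream. Absolute metric levels on synthetic
cohorts are therefore *not* predictions of hospital performance; the
package's claims are about the correctness and behaviour of the evaluation
machinery (monotonicity, conservation, calibration, time-saved
accounting).

## Numerical conventions

* Quartiles/medians: linear interpolation between order statistics
  (quantile type 7).
* Printed-table comparison uses half-up rounding to 2 decimals.
* Majority baseline: `max(admitted share, discharged share)` per stratum
  (both single-direction baselines are also exposed). In the reference
  regression table, two specialty rows' published majority cells are
  inconsistent with their own published counts; they are carried with a
  `majority_discordant` flag and excluded from that one assertion.
* Coherence crosstab cells with no TP visits are NaN (empty), never 0.
* Age bins are closed decade bins with an open ≥88 bin; arrival periods
  are half-open 6-hour windows.
* All randomness flows through explicit integer seeds; configuration
  without a seed is rejected before any computation.

## Problem sizes

Unit tests run on a shared 600-visit cohort; calibration checks use
50,000 visits and 100,000 decision-time draws (binomial 3·SE bands);
the conservation suite uses 5,000 visits; the multi-seed signal-recovery
check trains five full models on 10,000-visit cohorts; the acceptance
script evaluates a 10,000-visit cohort and calibrates on 50,000. These
sizes give stable quartile and prevalence estimates (SE of the admitted
fraction at n=50,000 is ≈0.002) while the whole suite completes in well
under a minute of compute.

## Known limitations

* The feature schema is a configurable stand-in; with a site-specific
  schema the snapshot builder accepts any static field / event-category
  layout, but the bundled defaults are the generator's categories.
* The lock-in simulator scores every visit at every grid point even after
  locking (the extra scores are ignored); this is wasteful but keeps the
  probability traces available for diagnostics.
* Decision "time saved" assumes the clinician would act on the model
  instantly; real deployments add reaction latency, so reported savings
  are upper bounds by construction.
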