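# Methods

This note documents the models, conventions and numerical choices behind
`wlgs`, in the order the pipeline runs.

## From raw logs to contact time

A badge record is `(epoch_start_s, detected_id, rssi_db, ax, ay, az)`.
Epochs are half-open 5-s intervals `[t, t+5)` anchored at local midnight;
off-grid timestamps are snapped to the nearest epoch start, with exact
halfway ties resolved toward the earlier epoch.  Snaps and malformed
lines are counted on the parsed `SensorLog` rather than silently dropped;
duplicate `(epoch, detected_id)` records keep the strongest signal.
Within-day clock drift of the badges is below 100 ms per the hardware's
base-station synchronization and is ignored after grid snapping;
cross-*system* drift (badge network vs external actigraphy) is handled
separately (see synchronization below).

**Presence threshold.** Signal amplitudes are recoded to presence (1) /
absence (0) by `rssi ≥ threshold`.  The default threshold is −∞ — any
received record counts as presence — because the radio itself only
registers badges in range (≤ 5 m); the threshold is exposed for stricter
analyses.

**Symmetrization.** Detection is directed and drops out independently in
each direction, so two rules are exposed:

* `union` (default for contact time): a pair is co-present in an epoch if
  *either* badge heard the other.  With per-direction detection
  probability p this recovers a fraction `1−(1−p)²` of true co-presence
  (≈ 0.998 at p = 0.953) and is the better estimator of true shared time;
  it also tolerates one badge's battery dying (the surviving badge still
  carries the pair).
* `mutual`: both directions required (recovers `p²`); reserved mainly for
  the congruence reliability metric, which is precisely about the gap
  between the two rules.

Neither rule is labeled "the" published variant: the source analyses do
not state which was used, so both are first-class.

`t_AB = 5 s × Σ_epochs co-presence` per unordered pair; `T = 5 s ×
n_epochs` of the session.  Crew and habitat sensors share one id
namespace, but only crew ids enter the contact tensor — crew–habitat
detections feed localization only.  A measurement day is *complete* when
its registration time reaches a configurable minimum (default 6 h);
incomplete days are flagged and excluded from the monitored cohesion
series by default, mirroring the battery-loss attrition seen in practice.
Epoch filtering (time-of-day window such as the 14:18–20:18 social
afternoon, and/or a per-member ACTIVE mask) zeroes a pair's co-presence
at epochs where either member fails the mask, while `T` tracks the
windowed epoch count.

## Sociometric indices

For a crew of size N, from a 2/1/0 choice table (value ≥ 1 counts as a
selection, mutual selection = both directed values ≥ 1):

* selection status `S_A = s_A/(N−1)`, rejection status `R_A = r_A/(N−1)`;
* crew cohesion `C = s_AB/(N(N−1)/2)` with `s_AB` the number of
  two-sided selections.

Rejection status requires an explicit rejections table: time spent
together indicates attraction but carries no rejection signal, so `R_A`
is never derived from proximity data.

`T_AB = t_AB/T`, and `CRTI = 10⁶ · Σ_pairs t_XY/(T·N(N−1)/2)` ppm — for
N = 6 the denominator pair count is 15, and CRTI is algebraically
`10⁶ × mean(T_AB)` (asserted as a property test).

**Time→choices recoding.** Per subject, partners are ranked by `t_AB`;
largest time → 2, second → 1, rest → 0, giving the N(N−1) directed cells
(30 for N = 6) that rank-correlate against questionnaires.  Ties are
broken deterministically toward the lexicographically smaller partner id
and flagged — reproducibility was preferred over randomization.  A
subject with no recorded time gets an all-zero row plus a flag.

**Subgroups.** "Dyadic/triadic/quadric interaction" is defined as a
*maximal clique* of the per-epoch co-presence graph: a subset of size k
accrues an epoch only when it is a clique and no superset is.  This makes
the k-layers mutually exclusive (a triad epoch contributes to no dyad),
which is the reading under which subgroup layers can be plotted as
separate bands.  The fast path caches maximal cliques per unique
adjacency pattern; tests compare it against exhaustive subset
enumeration.

**Star plot.** Subjects sit at fixed angles (2π/N spacing in sorted id
order from angle 0 — the assignment is a display convention) with radius
= that day's total crew-contact time; position `(t·sin α, t·cos α)`,
daily center = mean of positions, overall center = mean of daily centers.

## Reliability metrics

* **Congruence** = 100 × (#epochs registered in both directions) /
  (#epochs registered in at least one).  The denominator is the union of
  one-sided registrations: normalizing by all epochs would be diluted by
  mutual absence and could not approach the ~91% level any plausible
  detection noise produces.  Under independent per-direction detection
  at probability p the closed form is `100·p/(2−p)` (91.0% at
  p = 0.953), verified by simulation.
* **Binary pair correlation** — Pearson on the 0/1 series (equals the
  phi coefficient of the 2×2 table).
* **Localization** — per epoch, the habitat beacon heard with the
  strongest signal ("none" if no beacon heard).  **Video agreement**: a
  *detection* is a maximal run of consecutive epochs with a constant
  (video location, assigned location) state, counted in hourly bins;
  it fails when the assigned location differs from the video's.  The
  run-based definition makes counts event-like (tens per hour), matching
  how human annotators tally; a per-epoch mode is exposed as an
  alternative.  Unfilmed (private) intervals are excluded by simply not
  appearing in the annotation.  Per-bin percent = 100·(detections −
  failed)/detections; the summary row is the column sums.  Note a known
  inconsistency in the published worked example of such a table: its
  summary counts (261 detections, 11 failed) imply 95.8% correct while
  the printed summary row says 96.0% (95.7% elsewhere); the per-bin
  percentages are all consistent with their counts.  This package always
  recomputes the summary percentage from the counts.
* **Actigraphy synchronization** — per day, the internal (badge
  accelerometer) and external actigraph series are mean-centered and the
  lag maximizing their normalized cross-correlation is searched on the
  5-s epoch grid within ±10 min (default); the internal series is then
  re-stamped by that day-specific constant.  Flat series produce a
  warning and lag 0.

## Time series

* **Spline oversampling**: irregular series (twice-weekly badge days,
  biweekly ethology, monthly questionnaires) are resampled onto the
  integer-day grid with an *interpolating* natural cubic spline — the
  observed points stay fixed, which rules out smoothing splines — and
  never extrapolated outside the observed range.  At least 4 points are
  required.
* **Trend**: OLS of value on day; the standardized β of a simple
  regression equals the Pearson correlation, and β² = R².  Two-sided
  p-values throughout; no multiple-testing correction is applied —
  correlation tables are reported descriptively as raw r/p pairs.
* **Correlations** between daily series run over the intersection of
  their days (≥ 3 required), Pearson or Spearman; choice tables
  correlate by Spearman over their flattened directed cells.
* **ARIMA**: differencing order d = 1 by default (the cohesion series is
  trend-contaminated; lag-1 differences are treated as stationary), with
  p, q ≤ 3 selected by BIC — BIC's stronger penalty keeps white-noise-like
  series from attracting spurious AR/MA terms; AIC is available, as is a
  fixed-order fit.  Non-convergent candidates are skipped.  Residual
  ACF/PACF are reported for diagnostics.  Forecasts carry central
  prediction intervals (95% default).  The published forecasting figure's
  exact order/criterion/interval level is not recoverable, so forecasting
  quality is validated by properties (closed-form random-walk behavior,
  interval coverage, AR-coefficient recovery) rather than by matching a
  printed curve.

## The simulator

The generator emulates the study conditions: 6 crew badges + 6 room
beacons, 0.2 Hz epochs, twice-weekly (Tue/Fri) sessions starting on
mission day 15 of a 520-day mission, an 11-h session (09:18–20:18, within
the 20-h battery limit), per-direction per-epoch detection probability
0.953 (the level consistent with ~91% observed congruence), RSSI drawn
from a truncated normal in dB (distance is not modelled beyond
in-range/out-of-range), battery dropout truncating ~30% of logs at a
uniform time (matching the roughly one-third incomplete data sets seen in
the field), and a small whole-session loss rate (~1.5%).

No generative model of crew behavior was published, so the schedule is
the minimal structure that makes the validation logic exercisable: a
deterministic work roster dictates morning co-location (task-driven, not
preference-driven), while afternoon "gatherings" (mostly dyads, some
triads/quads, ~40 events/day, exponential durations around 10 min) are
sampled with probability and duration proportional to a latent pairwise
affinity matrix — higher affinity means both more frequent and longer
contacts, which is what makes latent-affinity rank recovery from
measured time a meaningful test.  Gatherings assign a shared room, so
contact implies co-location by construction; event times are snapped to
the epoch grid so ground-truth pair times are exactly recoverable at
detection probability 1.  Each member also gets a 20–40 min rest block
(the ACTIVE mask), and a per-member block-wise "exertion profile" feeds
both the badge accelerometer and the external actigraphy series, whose
clock is offset per day (N(0, 30 s) by default, or a fixed injected
value) to exercise synchronization.

Randomness: one master seed; every day draws from an independent
substream keyed by (seed, day), so datasets are byte-reproducible and
any single day can be regenerated in isolation.

What the simulator does *not* emulate — and what passing tests therefore
do not show about real data: radio propagation and distance-dependent
detection, correlated (non-independent) detection failures between the
two directions of a pair, badge-wearing compliance, genuine behavioral
dynamics (conflict, habituation, drift in affinities), and annotation
error in the video ground truth.  Tests against the simulator validate
the *computations*; they cannot validate the behavioral interpretation
of CRTI.

## Problem sizes and tolerances in the test suite

Tests run the pipeline on short missions (20–60 days, 4–13 sessions) and
single days, which exercise every code path at a few seconds per case;
statistical calibrations use 10 000-epoch detection series, 1000
white-noise correlation replicates, 200 forecast-coverage replicates and
100 random tensors for the subgroup oracle.  Stochastic assertions use
seeded generators with bands set from the relevant sampling error (e.g.
3 Monte-Carlo standard errors for congruence, ±0.15 for an AR(1)
coefficient at n = 400, [0.035, 0.065] for a nominal 0.05 type-I rate).

## Known limitations

* The trend check against the mission's deposited per-day CRTI table
  requires that published CSV, which is not redistributable here; the
  corresponding test states where to place it and fails (rather than
  skips) in its absence.
* Localization is argmax-RSSI per epoch; fast room crossings shorter
  than the 5-s epoch are invisible, and no hysteresis is applied.
* Latent-space / exponential-random-graph modelling of the valued
  contact network is out of scope, as are voice/physiological channels
  and raw video processing (only annotation interval files are
  consumed).
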