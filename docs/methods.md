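# Methods

## Scope

`alsonset` implements three things: (i) a composite disease-onset score for
longitudinal preclinical phenotype tables and its per-mouse onset detector;
(ii) the statistical stage used on such data (Kaplan–Meier onset curves,
log-rank Mantel–Cox and log-rank trend tests, Mann–Whitney onset comparison,
two-way ANOVA with Tukey HSD, Shapiro–Wilk, mean ± SEM summaries); and
(iii) a seeded synthetic-cohort generator calibrated to the four-group
SOD1-G93A treadmill study design so that every stage has inputs with known
ground truth. Wet-lab measurement procedures (histology, qPCR, imaging) are
out of scope; terminal measures enter only as per-mouse endpoint numbers.

## Composite score and onset

Indicators are evaluated per measurement day and not latched (a `latch`
option exists): a transient recovery clears the flag again. The deficit
criteria use strict inequality at the 20% boundary — weight exactly at
0.8 × reference does **not** score — implemented with a relative float
guard so that values landing exactly on the boundary after decimal round
trips are classified consistently. The ordinal rubric threshold "reached
4.75" is implemented as `score ≤ 4.75`, since rubric scores only worsen
downward from 5.

Two reference levels are not uniquely determined by the study description
and are therefore policy options, fixed per analysis run:

- **weight reference** — default is the contemporaneous *sedentary*-WT group
  mean (the group figures are drawn against); `pooled_wt` uses all WT mice.
- **grip reference** — default is the mouse's own running maximum of
  normalized grip (a "reduction of 20%" is read as relative to the best
  level the animal has shown); `baseline` (first-day value) and `wt_mean`
  are provided.

Onset is the first day whose composite total reaches the threshold (default
6 of 9) for `persistence` consecutive measurements (default 1; the sustained
option exists because transient single-day dips are conceivable under
observer noise). Mice that never qualify are right-censored at their last
observed day. Exactly 6 of the 16 indicator combinations can reach the
default threshold; all require at least one quantitative deficit or both
motor deficits plus one quantitative one, which is the point of the 3 / 1.5
weighting: blind observer scores alone cannot declare onset.

## Synthetic cohort

### Mean curves

All mean curves are piecewise linear, because the study reports breakpoint
ages and directions rather than curve shapes:

- **weight**: `w(t) = w₃₅ + β·(t − 35)` before the group's plateau day,
  constant after. Defaults: `w₃₅ = 17 g` (typical for 5-week female
  C57BL/6), `β = 0.10 g/day`; plateau at day 70 (trained G93A) and 77
  (sedentary G93A), none for WT.
- **normalized grip**: linear drift `g(t) = g₃₅ + σ·(t − 35)` in arbitrary
  consistent units (`g₃₅ = 5.0`); slopes +0.010/day for trained WT (training
  improves WT strength), 0 for sedentary WT, −0.028/day (sedentary G93A) and
  −0.038/day (trained G93A).
- **latent motor score** (reflex and gait separately): 5 before the group's
  decline-start day; on that day the score has dropped to the first impaired
  rubric level (4.75), then declines at `motor_decline_rate` (default
  0.05 score/day), floored at the humane-endpoint level 0.5. Anchoring the
  ramp at 4.75 *on* the decline-start day makes the first sub-normal
  observation — latent or discretized — land exactly on the configured
  decline age, which is what "the score started decreasing at day X" means
  on a twice-weekly grid. Decline starts: reflex 52 / 66 and gait 59 / 70
  days for trained / sedentary G93A; never for WT.

The default measurement grid alternates +3/+4 days from 35 to 91 (17
sessions, "twice a week"); every landmark age above falls on this grid.
Motor-skill tests are simulated on the same schedule as weight (their real
frequency is configurable through the design).

### Noise model

- Weight: a per-mouse Gaussian intercept offset (SD 1 g) plus independent
  per-day measurement noise (SD 0.4 g).
- Grip: per-mouse Gaussian offset of the latent normalized level (SD 0.25)
  plus per-attempt noise (SD 0.10 normalized units); the three recorded
  attempts are the (latent + noise) values multiplied by the recorded
  weight, so the scoring module's mean-of-three-over-weight normalization
  recovers the latent level and is exercised end to end.
- Motor scores: the latent curve is discretized to the nearest rubric level
  (ties round down, toward the worse score) and then perturbed by a
  symmetric ±1-level observer error with probability 0.10, clamped to the
  scale — a minimal ordinal-error model for blind qualitative scoring.
- Endpoint: per-mouse motor-neuron percentage is Gaussian per group
  (means 100 / 100 / 80 / 50 for SD-WT / TR-WT / SD-G93A / TR-G93A, SDs
  10 / 10 / 8 / 5), truncated to stay positive.

### Calibration of the free parameters

Breakpoint ages, group sizes, the schedule and the endpoint means are taken
directly from the study. The grip slopes are the one genuinely free pair:
no grip values are printed, so they were set once so that the 20% drop
against the running-max reference is crossed near each transgenic group's
reported mean onset age (grid day 63 for trained, between 70 and 73 for
sedentary G93A). Under the defaults grip is the binding indicator: reflex
and gait have already fired when the composite reaches 6, and the weight
indicator essentially never fires inside the 91-day window (the transgenic
deficit stays below 20% of the WT mean), mirroring a composite in which the
quantitative strength deficit completes the onset pattern. These defaults
are study conditions, not tuning dials.

### What the simulator does and does not emulate

It reproduces group-level trajectory shapes, landmark ages, measurement
cadence, observer error on ordinal scales and endpoint effect sizes. It
does **not** model within-mouse correlation of the four tests beyond the
shared weight factor, progressive-variance effects near end stage, dropout
before day 91, litter/cage effects, or any physiological link between
training dose and decline rates (the protocol's weekly distance is exposed
as a covariate only). Passing tests therefore validate the scoring and
statistics machinery under realistic but idealized inputs; they do not
certify behavior on real data with structured missingness.

## Statistics

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; Mann–Whitney and Shapiro–Wilk to `scipy.stats`; the factorial
ANOVA (type-II sums of squares — all types coincide on the balanced default
design) and Tukey HSD to `statsmodels`. The log-rank test for trend is
implemented in-package as the 1-df chi-square of the score-weighted sum of
observed-minus-expected events with the multivariate-hypergeometric
variance; with two groups scored 0/1 it reduces to the Mantel–Cox test,
which the test suite checks, along with exact permutation and enumeration
oracles at small n and a closed-form balanced-ANOVA oracle (agreement to
1e-8).

Mann–Whitney uses exact enumeration when both samples are tie-free with
min(n) ≤ 12, otherwise the mid-rank normal approximation with tie
correction — onset days live on a discrete grid, so ties are expected.
The onset comparison uses event times only (under the calibrated defaults
every transgenic mouse reaches onset by day 91). SEM is sd/√n with ddof = 1
and defined as 0 for n = 1. Tukey adjustment is applied within an ANOVA
family only; no study-wide multiplicity correction is applied.

## Numerical and design choices

- Degenerate inputs fail loudly: empty score series, no events in a
  log-rank test, constant samples in Shapiro–Wilk, cells with fewer than
  two observations in the interaction ANOVA, nonpositive reference levels.
- Rubric validation snaps CSV round-tripped scores to the level set with a
  1e-9 tolerance and rejects anything else, naming the offending value.
- `weight_plateau_day` returns the first scheduled day that no later value
  exceeds by more than `tol` (default 0); on a strictly increasing curve
  that is the last day, on a constant curve the first.
- Determinism: one `numpy` Generator seeded per cohort drives all draws in
  a fixed order; identical (design, params, seed) gives bit-identical
  tables, and the CLI writes a manifest with a config hash per stage.
- Problem sizes: the replication study uses 200 cohorts of 48 mice × 17
  days, which estimates the grand onset means to well under a tenth of a
  day of Monte-Carlo error; property tests use small-n instances where
  exact enumeration is feasible.

## Known limitations

- The latent motor process is common to all mice in a group (no per-mouse
  decline-age jitter); between-mouse onset spread comes from grip/weight
  noise and observer error. Real cohorts spread more.
- The asymptotic Mantel–Cox p-value is compared against exact permutation
  references only in regimes where the chi-square approximation is
  adequate; at n ≤ 8 with heavy discreteness the two can differ by a few
  hundredths, which is a property of the approximation, not of the
  implementation.
- The trend test assumes equally spaced default group scores 0..k−1 unless
  scores are supplied.
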