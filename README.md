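# alsonset

Composite disease-onset scoring and onset survival analysis for longitudinal
preclinical phenotyping in the SOD1-G93A mouse model of amyotrophic lateral
sclerosis (ALS), plus a calibrated synthetic-cohort simulator so the whole
pipeline can be exercised and validated without animal data.

It is aimed at researchers running (or re-analysing) preclinical intervention
studies — here, an 8-week intense treadmill endurance protocol started at 35
days of age in four groups (WT/G93A × sedentary/trained, n = 12 per group,
phenotyped twice a week until day 91) — who need a reproducible, scriptable
implementation of a composite onset definition and its downstream statistics.

## The scoring model

At every measurement day *t*, four binary impairment indicators are computed
per mouse:

- **weight**: `I_W = 1` iff body weight `w(t) < 0.8 · w̄_WT(t)`, the
  contemporaneous sedentary-WT group mean (pooled-WT optional);
- **grip**: `I_G = 1` iff normalized grip strength (mean of three attempts
  divided by body weight) is `< 0.8 ·` the mouse's reference level (default:
  its own running maximum; first-day baseline and WT-mean are options);
- **reflex** and **gait**: `I_R, I_Ga = 1` iff the ordinal rubric score
  (levels 5, 4.75, 4.5, 4, 3.5, …, 0.5) has reached 4.75.

The composite score weights the quantitative tests by 3 and the
observer-rated tests by 1.5:

```
S(t) = 3·I_W + 3·I_G + 1.5·I_R + 1.5·I_Ga  ∈ {0, 1.5, 3, 4.5, 6, 7.5, 9}
```

Disease onset is the first day with `S(t) ≥ 6`; mice that never reach it are
right-censored at their last observation. Onset distributions are compared
with Kaplan–Meier curves, the log-rank (Mantel–Cox) test, a log-rank test for
trend and the Mann–Whitney U test; endpoint measures (e.g. the percentage of
ventral-horn motor neurons) go through a two-way genotype × activity ANOVA
with Tukey HSD post hoc tests and Shapiro–Wilk normality checks. Summaries
are reported as mean ± SEM.

The simulator draws piecewise-linear group trajectories (weight growth with a
transgenic plateau, linear grip drift, latent motor decline discretized onto
the rubric with a symmetric ±1-level observer-error model) whose calibrated
defaults reproduce the study's landmark ages exactly in the noise-free limit;
see `docs/methods.md` for the model and calibration details.

## Worked example

```sh
alsonset --quiet simulate --seed 1 --out demo
alsonset --quiet score demo/longitudinal.csv --out demo
alsonset --quiet onset demo/scores.csv --out demo
alsonset --quiet stats demo/onsets.csv --endpoint demo/endpoint.csv --out demo
alsonset --quiet report --dir demo
```

prints:

```
groups: 4
  sedentary G93A: 12/12 onsets, mean onset day 72.75
  trained G93A: 12/12 onsets, mean onset day 63.17
  sedentary WT: 0/12 onsets (all censored at day 91)
  trained WT: 0/12 onsets (all censored at day 91)
  logrank (Mantel-Cox): statistic=25.06 p=5.552e-07
  logrank trend: statistic=58.54 p=1.993e-14
  Mann-Whitney U (asymptotic): statistic=144 p=1.915e-05
  two-way ANOVA mn_pct [genotype]: statistic=142.8 p=2.091e-15
  ...
```

Every transgenic mouse reaches the composite threshold before day 91 while
no WT mouse does; training advances the mean onset of G93A mice by roughly
ten days in this cohort, and the log-rank and Mann–Whitney tests reject
equality of the two transgenic onset distributions. The ANOVA on the
simulated endpoint shows the genotype × activity interaction: training costs
trained G93A mice an extra ~28 percentage points of motor neurons (Tukey
SD-G93A vs TR-G93A) but does not change WT counts (Tukey SD-WT vs TR-WT,
p ≈ 0.85).

The same pipeline runs on real lab exports: any CSV with columns
`mouse_id, genotype, activity, day, weight_g, grip1, grip2, grip3,
reflex_score, gait_score` can be fed to `alsonset score`.

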