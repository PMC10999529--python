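"""Onset survival analysis and group statistics.

Kaplan-Meier product-limit curves and the two-group log-rank (Mantel-Cox)
test are delegated to lifelines; the log-rank test for trend over ordered
groups is implemented here (1-df chi-square on the score-weighted sum of
observed-minus-expected events, with the usual hypergeometric variance).
Mann-Whitney, Shapiro-Wilk and the two-way factorial ANOVA with Tukey HSD
go through scipy / statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate on the observed time grid."""

    times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    censored: tuple[int, ...]
    survival: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival probabilities must be nonincreasing in [0, 1]")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    sem: float
    n: int


def _as_time_event(times: Sequence[float], events: Sequence[int]):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty record set")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    return t, e


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit survival estimate from event/censoring times."""
    t, e = _as_time_event(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    obs_times = [float(x) for x in np.unique(t)]
    surv = kmf.survival_function_at_times(obs_times).to_numpy()
    return SurvivalCurve(
        times=tuple(obs_times),
        at_risk=tuple(int(table.loc[x, "at_risk"]) for x in obs_times),
        events=tuple(int(table.loc[x, "observed"]) for x in obs_times),
        censored=tuple(int(table.loc[x, "censored"]) for x in obs_times),
        survival=tuple(float(s) for s in surv),
    )


def logrank(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> TestResult:
    """Two-group log-rank (Mantel-Cox) test; 1-df chi-square."""
    ta, ea = _as_time_event(times_a, events_a)
    tb, eb = _as_time_event(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined without any events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        method="logrank (Mantel-Cox)",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n=(len(ta), len(tb)),
    )


def logrank_trend(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
    scores: Sequence[float] | None = None,
) -> TestResult:
    """Log-rank test for trend across ordered groups.

    ``groups`` is an ordered sequence of (times, events); ``scores`` the
    numeric group scores (default 0, 1, 2, ...).  Statistic:
    ``[sum_g c_g (O_g - E_g)]^2 / Var`` with the hypergeometric covariance
    accumulated over distinct event times; chi-square with 1 df.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if scores is None:
        scores = list(range(len(groups)))
    c = np.asarray(scores, dtype=float)
    if len(c) != len(groups):
        raise ValueError("one score per group required")

    parsed = [_as_time_event(t, e) for t, e in groups]
    all_t = np.concatenate([t for t, _ in parsed])
    all_e = np.concatenate([e for _, e in parsed])
    gidx = np.concatenate(
        [np.full(len(t), i) for i, (t, _) in enumerate(parsed)]
    )
    if all_e.sum() == 0:
        raise ValueError("log-rank trend test undefined without any events")

    event_times = np.unique(all_t[all_e == 1])
    k = len(groups)
    z = 0.0
    var = 0.0
    for tj in event_times:
        at_risk = all_t >= tj
        n_j = at_risk.sum()
        d_j = int(((all_t == tj) & (all_e == 1)).sum())
        if n_j < 2:
            continue
        n_gj = np.array([(at_risk & (gidx == g)).sum() for g in range(k)],
                        dtype=float)
        d_gj = np.array(
            [(((all_t == tj) & (all_e == 1)) & (gidx == g)).sum()
             for g in range(k)], dtype=float,
        )
        e_gj = d_j * n_gj / n_j
        z += float(c @ (d_gj - e_gj))
        # multivariate hypergeometric covariance of d_gj
        p = n_gj / n_j
        cov = d_j * (n_j - d_j) / (n_j - 1) * (np.diag(p) - np.outer(p, p))
        var += float(c @ cov @ c)

    if var <= 0:
        return TestResult(
            method="logrank trend", statistic=0.0, p_value=1.0,
            n=tuple(len(t) for t, _ in parsed),
        )
    chi2 = z * z / var
    return TestResult(
        method="logrank trend",
        statistic=float(chi2),
        p_value=float(sps.chi2.sf(chi2, df=1)),
        n=tuple(len(t) for t, _ in parsed),
    )


def mann_whitney(
    onsets_a: Sequence[float],
    onsets_b: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U comparison of onset ages.

    ``mode='auto'``: exact enumeration when both samples are small (min n
    <= 12) and tie-free; otherwise the normal approximation with mid-rank
    tie correction.  Onset days sit on a discrete grid, so ties are common.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "auto":
        method = "exact" if (min(a.size, b.size) <= 12 and not has_ties) \
            else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if method == "exact" and has_ties:
        raise ValueError("exact mode is not defined in the presence of ties")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        method=f"Mann-Whitney U ({method})",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(a.size, b.size),
    )


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    sum_sq: float
    df: float
    F: float
    p_value: float


def two_way_anova(
    values: Sequence[float],
    factor_genotype: Sequence[str],
    factor_activity: Sequence[str],
) -> dict[str, AnovaEffect]:
    """Two-way factorial ANOVA with interaction (genotype x activity).

    Type-II sums of squares; on the balanced designs used here all
    sums-of-squares types coincide.
    """
    d = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": list(factor_genotype),
            "activity": list(factor_activity),
        }
    )
    cell_sizes = d.groupby(["genotype", "activity"]).size()
    if (cell_sizes < 2).any():
        raise ValueError("need >= 2 observations per cell for the "
                         "interaction model")
    model = smf.ols("value ~ C(genotype) * C(activity)", data=d).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=2)
    key_map = {
        "C(genotype)": "genotype",
        "C(activity)": "activity",
        "C(genotype):C(activity)": "interaction",
    }
    out: dict[str, AnovaEffect] = {}
    for row_name, effect in key_map.items():
        row = table.loc[row_name]
        f = float(row["F"])
        p = float(row["PR(>F)"])
        out[effect] = AnovaEffect(
            effect=effect,
            sum_sq=float(row["sum_sq"]),
            df=float(row["df"]),
            F=0.0 if np.isnan(f) else f,
            p_value=1.0 if np.isnan(p) else p,
        )
    return out


def tukey_hsd(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> list[TestResult]:
    """Tukey studentized-range adjusted pairwise comparisons."""
    res = pairwise_tukeyhsd(
        np.asarray(values, dtype=float), np.asarray(groups), alpha=alpha
    )
    i1, i2 = res._multicomp.pairindices
    pairs = zip(res.groupsunique[i1], res.groupsunique[i2])
    return [
        TestResult(
            method=f"Tukey HSD {g1} vs {g2}",
            statistic=float(diff),
            p_value=float(min(max(p, 0.0), 1.0)),
        )
        for (g1, g2), diff, p in zip(pairs, res.meandiffs, res.pvalues)
    ]


def shapiro_wilk(sample: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample is degenerate (all values identical)")
    w, p = sps.shapiro(x)
    return TestResult(
        method="Shapiro-Wilk", statistic=float(w), p_value=float(p),
        n=(x.size,),
    )


def group_summary(values_by_group: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean and SEM (sd/sqrt(n), ddof=1; SEM=0 for n=1) per group."""
    out = []
    for group, values in values_by_group.items():
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            raise ValueError(f"empty group: {group!r}")
        sem = 0.0 if x.size == 1 else float(np.std(x, ddof=1) / np.sqrt(x.size))
        out.append(GroupSummary(group=str(group), mean=float(np.mean(x)),
                                sem=sem, n=int(x.size)))
    return out
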