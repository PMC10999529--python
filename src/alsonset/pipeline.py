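"""Stage functions tying simulation, scoring and statistics together.

Each stage consumes and produces the documented CSV tables, so the pipeline
can be driven from Python or from the command line stage by stage, and a
fixed (config, seed) pair always yields byte-identical data outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .config import PipelineConfig, RunManifest
from .design import GROUPS, group_label
from .scoring import ReferencePolicy, onset_table, score_table
from .simulate import simulate_cohort
from .stats import (
    group_summary,
    kaplan_meier,
    logrank,
    logrank_trend,
    mann_whitney,
    shapiro_wilk,
    tukey_hsd,
    two_way_anova,
)
from .trajectories import TrajectoryParams

log = logging.getLogger("alsonset")

try:
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("alsonset")
except Exception:  # pragma: no cover - not installed
    _VERSION = "unknown"


def _manifest(stage: str, config: PipelineConfig, seed: int, t0: float,
              outputs: list[Path], outdir: Path) -> None:
    RunManifest(
        stage=stage,
        seed=int(seed),
        config_hash=config.config_hash(),
        package_version=_VERSION,
        elapsed_s=round(time.perf_counter() - t0, 4),
        outputs=[str(p) for p in outputs],
    ).write(outdir / f"manifest_{stage}.json")


def cmd_simulate(config: PipelineConfig, seed: int | None = None,
                 outdir: str | Path | None = None) -> dict[str, Path]:
    """Simulate a cohort and write longitudinal + endpoint CSVs."""
    t0 = time.perf_counter()
    seed = config.design.seed if seed is None else int(seed)
    outdir = Path(outdir if outdir is not None else config.output_dir)
    longitudinal, endpoint = simulate_cohort(
        config.design, config.params, seed=seed
    )
    paths = {
        "longitudinal": aio.write_csv(longitudinal, outdir / "longitudinal.csv"),
        "endpoint": aio.write_csv(endpoint, outdir / "endpoint.csv"),
    }
    log.info("stage=simulate seed=%d rows_out=%d", seed, len(longitudinal))
    _manifest("simulate", config, seed, t0, list(paths.values()), outdir)
    return paths


def cmd_score(longitudinal_csv: str | Path, config: PipelineConfig,
              outdir: str | Path | None = None) -> dict[str, Path]:
    """Score a longitudinal CSV into per-day indicators and totals."""
    t0 = time.perf_counter()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    longitudinal = aio.read_longitudinal(longitudinal_csv)
    scores = score_table(longitudinal, config.policy)
    paths = {"scores": aio.write_csv(scores, outdir / "scores.csv")}
    log.info("stage=score rows_in=%d rows_out=%d",
             len(longitudinal), len(scores))
    _manifest("score", config, config.design.seed, t0,
              list(paths.values()), outdir)
    return paths


def cmd_onset(scores_csv: str | Path, config: PipelineConfig,
              outdir: str | Path | None = None) -> dict[str, Path]:
    """Detect per-mouse onset/censoring from a score CSV."""
    t0 = time.perf_counter()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    scores = aio.read_scores(scores_csv)
    onsets = onset_table(scores, threshold=config.threshold,
                         persistence=config.persistence)
    paths = {"onsets": aio.write_csv(onsets, outdir / "onsets.csv")}
    log.info("stage=onset rows_in=%d mice=%d", len(scores), len(onsets))
    _manifest("onset", config, config.design.seed, t0,
              list(paths.values()), outdir)
    return paths


def cmd_stats(onset_csv: str | Path, endpoint_csv: str | Path | None,
              config: PipelineConfig,
              outdir: str | Path | None = None) -> dict[str, Path]:
    """Survival curves, tests and summaries from onset (+ endpoint) CSVs."""
    t0 = time.perf_counter()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    onsets = aio.read_onsets(onset_csv)

    km_rows = []
    for genotype, activity in GROUPS:
        sub = onsets[(onsets["genotype"] == genotype)
                     & (onsets["activity"] == activity)]
        if sub.empty:
            continue
        curve = kaplan_meier(sub["time_days"], sub["event"])
        label = group_label(genotype, activity)
        for i in range(len(curve.times)):
            km_rows.append(
                {
                    "group": label,
                    "time": curve.times[i],
                    "at_risk": curve.at_risk[i],
                    "events": curve.events[i],
                    "survival": curve.survival[i],
                }
            )
    km_df = pd.DataFrame(km_rows)

    test_rows = []
    sd = onsets[(onsets["genotype"] == "G93A")
                & (onsets["activity"] == "sedentary")]
    tr = onsets[(onsets["genotype"] == "G93A")
                & (onsets["activity"] == "trained")]
    if not sd.empty and not tr.empty and (sd["event"].sum() + tr["event"].sum()):
        res = logrank(sd["time_days"], sd["event"], tr["time_days"], tr["event"])
        test_rows.append({"method": res.method, "statistic": res.statistic,
                          "p_value": res.p_value,
                          "groups": "SD-G93A vs TR-G93A"})
        groups_ordered = []
        labels = []
        for genotype, activity in GROUPS:
            sub = onsets[(onsets["genotype"] == genotype)
                         & (onsets["activity"] == activity)]
            if not sub.empty:
                groups_ordered.append(
                    (sub["time_days"].tolist(), sub["event"].tolist())
                )
                labels.append(group_label(genotype, activity))
        if len(groups_ordered) >= 2:
            res = logrank_trend(groups_ordered)
            test_rows.append({"method": res.method, "statistic": res.statistic,
                              "p_value": res.p_value,
                              "groups": " < ".join(labels)})
        sd_events = sd.loc[sd["event"] == 1, "time_days"]
        tr_events = tr.loc[tr["event"] == 1, "time_days"]
        if len(sd_events) and len(tr_events):
            res = mann_whitney(sd_events, tr_events)
            test_rows.append({"method": res.method, "statistic": res.statistic,
                              "p_value": res.p_value,
                              "groups": "SD-G93A vs TR-G93A onset (events)"})

    summary_rows = []
    for genotype, activity in GROUPS:
        sub = onsets[(onsets["genotype"] == genotype)
                     & (onsets["activity"] == activity)]
        events = sub.loc[sub["event"] == 1, "time_days"]
        if len(events) == 0:
            continue
        for s in group_summary({group_label(genotype, activity): events}):
            summary_rows.append(
                {"group": s.group, "measure": "onset_day",
                 "mean": s.mean, "sem": s.sem, "n": s.n}
            )

    if endpoint_csv is not None:
        endpoint = aio.read_endpoint(endpoint_csv)
        cells = endpoint.groupby(["genotype", "activity"]).size()
        if len(cells) == 4 and (cells >= 2).all():
            effects = two_way_anova(endpoint["mn_pct"], endpoint["genotype"],
                                    endpoint["activity"])
            for eff in effects.values():
                test_rows.append(
                    {"method": f"two-way ANOVA mn_pct [{eff.effect}]",
                     "statistic": eff.F, "p_value": eff.p_value,
                     "groups": "all"}
                )
            labels = endpoint.apply(
                lambda r: group_label(r["genotype"], r["activity"]), axis=1
            )
            for res in tukey_hsd(endpoint["mn_pct"], labels):
                test_rows.append({"method": res.method,
                                  "statistic": res.statistic,
                                  "p_value": res.p_value, "groups": "pairwise"})
            for label in sorted(labels.unique()):
                values = endpoint.loc[labels == label, "mn_pct"]
                if values.nunique() > 1 and len(values) >= 3:
                    res = shapiro_wilk(values)
                    test_rows.append({"method": f"Shapiro-Wilk mn_pct {label}",
                                      "statistic": res.statistic,
                                      "p_value": res.p_value, "groups": label})
                for s in group_summary({label: values}):
                    summary_rows.append(
                        {"group": s.group, "measure": "mn_pct",
                         "mean": s.mean, "sem": s.sem, "n": s.n}
                    )

    paths = {
        "km": aio.write_csv(km_df, outdir / "km.csv"),
        "tests": aio.write_csv(pd.DataFrame(test_rows), outdir / "tests.csv"),
        "summary": aio.write_csv(pd.DataFrame(summary_rows),
                                 outdir / "summary.csv"),
    }
    log.info("stage=stats mice=%d tests=%d", len(onsets), len(test_rows))
    _manifest("stats", config, config.design.seed, t0,
              list(paths.values()), outdir)
    return paths


def run_all(config: PipelineConfig, seed: int | None = None,
            outdir: str | Path | None = None) -> dict[str, Path]:
    """simulate -> score -> onset -> stats on one cohort."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    paths = cmd_simulate(config, seed=seed, outdir=outdir)
    paths.update(cmd_score(paths["longitudinal"], config, outdir=outdir))
    paths.update(cmd_onset(paths["scores"], config, outdir=outdir))
    paths.update(cmd_stats(paths["onsets"], paths["endpoint"], config,
                           outdir=outdir))
    return paths


@dataclass(frozen=True)
class StudyReplication:
    """Aggregate results of many simulated cohorts under one design."""

    n_cohorts: int
    onset_means: dict[str, float]        # grand mean onset day per group label
    onset_mean_diff: float               # sedentary - trained G93A
    mn_reduction: dict[str, float]       # % reduction vs SD-WT, mean over seeds
    per_seed_diffs: tuple[float, ...]    # per-cohort SD-TR G93A onset diffs


def replicate_study(
    n_cohorts: int = 200,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> StudyReplication:
    """Run the full scoring pipeline on ``n_cohorts`` simulated cohorts.

    Onset ages are averaged over observed events (under the calibrated
    defaults every transgenic mouse reaches onset before day 91); motor
    neuron reductions are per-seed percentages vs the sedentary-WT mean,
    averaged across seeds.
    """
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(int(seed))
    cohort_seeds = rng.integers(0, 2**31 - 1, size=int(n_cohorts))

    onset_times: dict[str, list[float]] = {
        group_label(g, a): [] for g, a in GROUPS
    }
    diffs: list[float] = []
    reductions: dict[str, list[float]] = {"SD-G93A": [], "TR-G93A": []}

    for s in cohort_seeds:
        longitudinal, endpoint = simulate_cohort(
            config.design, config.params, seed=int(s)
        )
        scores = score_table(longitudinal, config.policy)
        onsets = onset_table(scores, threshold=config.threshold,
                             persistence=config.persistence)
        onsets["label"] = [
            group_label(g, a)
            for g, a in zip(onsets["genotype"], onsets["activity"])
        ]
        per_group: dict[str, float] = {}
        for label, sub in onsets.groupby("label"):
            events = sub.loc[sub["event"] == 1, "time_days"]
            onset_times[label].extend(float(t) for t in events)
            if len(events):
                per_group[label] = float(events.mean())
        if "SD-G93A" in per_group and "TR-G93A" in per_group:
            diffs.append(per_group["SD-G93A"] - per_group["TR-G93A"])

        sd_wt = endpoint.loc[
            (endpoint["genotype"] == "WT")
            & (endpoint["activity"] == "sedentary"), "mn_pct"
        ].mean()
        for label, (g, a) in (("SD-G93A", ("G93A", "sedentary")),
                              ("TR-G93A", ("G93A", "trained"))):
            grp = endpoint.loc[
                (endpoint["genotype"] == g) & (endpoint["activity"] == a),
                "mn_pct",
            ].mean()
            reductions[label].append(100.0 * (1.0 - grp / sd_wt))

    onset_means = {
        label: float(np.mean(times)) for label, times in onset_times.items()
        if len(times)
    }
    return StudyReplication(
        n_cohorts=int(n_cohorts),
        onset_means=onset_means,
        onset_mean_diff=(
            onset_means.get("SD-G93A", float("nan"))
            - onset_means.get("TR-G93A", float("nan"))
        ),
        mn_reduction={k: float(np.mean(v)) for k, v in reductions.items()},
        per_seed_diffs=tuple(diffs),
    )
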