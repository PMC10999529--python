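"""Composite impairment scoring and onset detection.

Four binary impairment indicators are evaluated at every measurement day:

* weight  -- body weight more than 20% below the WT reference mean that day;
* grip    -- normalized grip strength (mean of three attempts / body weight)
             more than 20% below the mouse's reference level;
* reflex  -- hind-limb extension-reflex rubric score at or below 4.75;
* gait    -- gait rubric score at or below 4.75.

The quantitative indicators (weight, grip) carry weight 3, the observer-rated
ones (reflex, gait) weight 1.5, giving a composite score in {0, 1.5, ..., 9}.
Disease onset is the first measurement day at which the composite reaches 6;
a mouse that never reaches it is right-censored at its last observation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .trajectories import RUBRIC_LEVELS

WEIGHT_WEIGHT = 3.0
GRIP_WEIGHT = 3.0
REFLEX_WEIGHT = 1.5
GAIT_WEIGHT = 1.5

MOTOR_IMPAIRMENT_LEVEL = 4.75  # rubric level at/below which a test scores 1
RELATIVE_DEFICIT = 0.20        # the "20% lower" criterion
DEFAULT_THRESHOLD = 6.0

INDICATOR_NAMES = ("weight", "grip", "reflex", "gait")

_LEVELS = np.asarray(RUBRIC_LEVELS)


@dataclass(frozen=True)
class IndicatorVector:
    """Binary impairment flags at one measurement day."""

    day: int
    i_weight: int
    i_grip: int
    i_reflex: int
    i_gait: int

    def __post_init__(self) -> None:
        for name in ("i_weight", "i_grip", "i_reflex", "i_gait"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class CompositeScore:
    """Weighted composite impairment score at one day."""

    day: int
    total: float
    components: tuple[float, float, float, float]  # weight, grip, reflex, gait


@dataclass(frozen=True)
class OnsetRecord:
    """Per-mouse onset event or right-censoring."""

    mouse_id: str
    event: bool
    time: int  # onset day if event, else last observed day


@dataclass(frozen=True)
class ReferencePolicy:
    """How the 100% reference levels for weight and grip are defined.

    weight_ref
        ``sedentary_wt`` -- contemporaneous sedentary-WT group mean (default);
        ``pooled_wt`` -- mean over all WT mice that day.
    grip_ref
        ``running_max`` -- the mouse's own running maximum of normalized grip
        up to the current day (default); ``baseline`` -- its first-day value;
        ``wt_mean`` -- contemporaneous pooled-WT mean normalized grip.
    latch
        If true, an indicator that has fired once stays on at later days.
    """

    weight_ref: Literal["sedentary_wt", "pooled_wt"] = "sedentary_wt"
    grip_ref: Literal["running_max", "baseline", "wt_mean"] = "running_max"
    latch: bool = False

    def __post_init__(self) -> None:
        if self.weight_ref not in ("sedentary_wt", "pooled_wt"):
            raise ValueError(f"unknown weight_ref: {self.weight_ref!r}")
        if self.grip_ref not in ("running_max", "baseline", "wt_mean"):
            raise ValueError(f"unknown grip_ref: {self.grip_ref!r}")


def normalize_grip(attempts: Sequence[float], weight: float) -> float:
    """Mean of the three grip attempts divided by body weight."""
    if len(attempts) != 3:
        raise ValueError(f"expected 3 grip attempts, got {len(attempts)}")
    if weight <= 0:
        raise ValueError("weight must be positive")
    return float(np.mean(attempts)) / float(weight)


def _strictly_below(value, cutoff):
    """value < cutoff, robust to float noise exactly at the boundary."""
    return (value < cutoff) & ~np.isclose(value, cutoff, rtol=1e-9, atol=0.0)


def weight_indicator(w: float, ref: float) -> int:
    """1 iff weight is more than 20% below the reference mean (w < 0.8 ref)."""
    if ref <= 0:
        raise ValueError("weight reference must be positive")
    return int(_strictly_below(w, (1.0 - RELATIVE_DEFICIT) * ref))


def grip_indicator(g_t: float, baseline: float) -> int:
    """1 iff normalized grip is more than 20% below the baseline level."""
    if baseline <= 0:
        raise ValueError("grip baseline must be positive")
    return int(_strictly_below(g_t, (1.0 - RELATIVE_DEFICIT) * baseline))


def _check_rubric(score: float) -> float:
    matches = np.isclose(score, _LEVELS, rtol=0.0, atol=1e-9)
    if not matches.any():
        raise ValueError(f"{score!r} is not a rubric level {RUBRIC_LEVELS}")
    return float(_LEVELS[int(np.argmax(matches))])


def motor_indicator(score: float) -> int:
    """1 iff the rubric score has reached 4.75 (i.e. score <= 4.75)."""
    return int(_check_rubric(score) <= MOTOR_IMPAIRMENT_LEVEL)


def composite_score(iv: IndicatorVector) -> CompositeScore:
    """Weighted total: 3*(weight + grip) + 1.5*(reflex + gait)."""
    components = (
        WEIGHT_WEIGHT * iv.i_weight,
        GRIP_WEIGHT * iv.i_grip,
        REFLEX_WEIGHT * iv.i_reflex,
        GAIT_WEIGHT * iv.i_gait,
    )
    return CompositeScore(day=iv.day, total=float(sum(components)),
                          components=components)


def onset_reaching_combinations(
    threshold: float = DEFAULT_THRESHOLD,
) -> set[frozenset[str]]:
    """All indicator combinations whose composite total reaches ``threshold``.

    Brute force over the 16 possible indicator vectors; diagnostic for
    understanding which deficit patterns can trigger onset.
    """
    reached = set()
    for flags in itertools.product((0, 1), repeat=4):
        iv = IndicatorVector(0, *flags)
        if composite_score(iv).total >= threshold:
            reached.add(
                frozenset(
                    name for name, f in zip(INDICATOR_NAMES, flags) if f
                )
            )
    return reached


def detect_onset(
    days: Sequence[int],
    totals: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    persistence: int = 1,
    mouse_id: str = "",
) -> OnsetRecord:
    """First day from which the composite stays at/above threshold.

    With ``persistence`` k, onset requires k consecutive qualifying
    measurements starting at the onset day; otherwise the mouse is censored
    at its last observed day.
    """
    days = list(days)
    totals = list(totals)
    if len(days) == 0:
        raise ValueError("empty score series")
    if len(days) != len(totals):
        raise ValueError("days and totals must have equal length")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    if not 0 < threshold <= 9:
        raise ValueError("threshold must be in (0, 9]")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    meets = [t >= threshold for t in totals]
    for i in range(len(days) - persistence + 1):
        if all(meets[i : i + persistence]):
            return OnsetRecord(mouse_id=mouse_id, event=True, time=int(days[i]))
    return OnsetRecord(mouse_id=mouse_id, event=False, time=int(days[-1]))


def score_table(
    longitudinal: pd.DataFrame,
    policy: ReferencePolicy | None = None,
) -> pd.DataFrame:
    """Per-row indicators and composite totals for a longitudinal table.

    Returns a frame with one row per mouse x day carrying the normalized
    grip, the reference levels used, the four indicators and the total.
    """
    if policy is None:
        policy = ReferencePolicy()
    required = {"mouse_id", "genotype", "activity", "day", "weight_g",
                "grip1", "grip2", "grip3", "reflex_score", "gait_score"}
    missing = required - set(longitudinal.columns)
    if missing:
        raise ValueError(f"longitudinal table is missing columns: "
                         f"{sorted(missing)}")

    df = longitudinal.sort_values(["mouse_id", "day"]).reset_index(drop=True)
    for col in ("reflex_score", "gait_score"):
        df[col] = df[col].map(_check_rubric)
    if (df["weight_g"] <= 0).any():
        raise ValueError("weight_g must be positive")
    if df.duplicated(["mouse_id", "day"]).any():
        raise ValueError("duplicate mouse_id x day rows")

    df["norm_grip"] = (
        df[["grip1", "grip2", "grip3"]].mean(axis=1) / df["weight_g"]
    )

    # weight reference: contemporaneous WT mean
    if policy.weight_ref == "sedentary_wt":
        ref_mask = (df["genotype"] == "WT") & (df["activity"] == "sedentary")
    else:
        ref_mask = df["genotype"] == "WT"
    if not ref_mask.any():
        raise ValueError("no WT reference mice found for the weight criterion")
    wt_weight = df.loc[ref_mask].groupby("day")["weight_g"].mean()
    df["weight_ref"] = df["day"].map(wt_weight)
    if df["weight_ref"].isna().any():
        raise ValueError("weight reference undefined for some measurement days")

    # grip reference per policy
    if policy.grip_ref == "running_max":
        df["grip_ref"] = df.groupby("mouse_id")["norm_grip"].cummax()
    elif policy.grip_ref == "baseline":
        df["grip_ref"] = df.groupby("mouse_id")["norm_grip"].transform("first")
    else:  # wt_mean
        wt_grip = (
            df.loc[df["genotype"] == "WT"].groupby("day")["norm_grip"].mean()
        )
        df["grip_ref"] = df["day"].map(wt_grip)
        if df["grip_ref"].isna().any():
            raise ValueError("grip reference undefined for some measurement days")
    if (df["grip_ref"] <= 0).any():
        raise ValueError("nonpositive grip reference encountered")

    factor = 1.0 - RELATIVE_DEFICIT
    df["i_weight"] = _strictly_below(
        df["weight_g"].to_numpy(), factor * df["weight_ref"].to_numpy()
    ).astype(int)
    df["i_grip"] = _strictly_below(
        df["norm_grip"].to_numpy(), factor * df["grip_ref"].to_numpy()
    ).astype(int)
    df["i_reflex"] = (df["reflex_score"] <= MOTOR_IMPAIRMENT_LEVEL).astype(int)
    df["i_gait"] = (df["gait_score"] <= MOTOR_IMPAIRMENT_LEVEL).astype(int)

    if policy.latch:
        for col in ("i_weight", "i_grip", "i_reflex", "i_gait"):
            df[col] = df.groupby("mouse_id")[col].cummax()

    df["total"] = (
        WEIGHT_WEIGHT * df["i_weight"]
        + GRIP_WEIGHT * df["i_grip"]
        + REFLEX_WEIGHT * df["i_reflex"]
        + GAIT_WEIGHT * df["i_gait"]
    )
    return df[
        ["mouse_id", "genotype", "activity", "day", "norm_grip",
         "weight_ref", "grip_ref",
         "i_weight", "i_grip", "i_reflex", "i_gait", "total"]
    ]


def onset_table(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    persistence: int = 1,
) -> pd.DataFrame:
    """Per-mouse onset records from a score table.

    Columns: mouse_id, genotype, activity, event (0/1), time_days.
    """
    required = {"mouse_id", "genotype", "activity", "day", "total"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table is missing columns: {sorted(missing)}")
    rows = []
    for mouse_id, sub in scores.sort_values("day").groupby("mouse_id", sort=True):
        rec = detect_onset(
            sub["day"].tolist(), sub["total"].tolist(),
            threshold=threshold, persistence=persistence, mouse_id=mouse_id,
        )
        rows.append(
            {
                "mouse_id": mouse_id,
                "genotype": sub["genotype"].iloc[0],
                "activity": sub["activity"].iloc[0],
                "event": int(rec.event),
                "time_days": rec.time,
            }
        )
    return pd.DataFrame(rows)


def weight_plateau_day(
    days: Sequence[int], values: Sequence[float], tol: float = 0.0
) -> int:
    """First scheduled day after which the curve never rises above it + tol."""
    days = list(days)
    values = list(values)
    if len(days) == 0:
        raise ValueError("empty curve")
    if len(days) != len(values):
        raise ValueError("days and values must have equal length")
    for i, v in enumerate(values):
        if all(later <= v + tol for later in values[i + 1:]):
            return int(days[i])
    raise AssertionError("unreachable: the last day always qualifies")


def decline_onset_day(
    days: Sequence[int], values: Sequence[float]
) -> Optional[int]:
    """First scheduled day with mean score below 5; None if never."""
    days = list(days)
    values = list(values)
    if len(days) == 0:
        raise ValueError("empty curve")
    if len(days) != len(values):
        raise ValueError("days and values must have equal length")
    for d, v in zip(days, values):
        if v < 5.0:
            return int(d)
    return None
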