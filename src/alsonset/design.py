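"""Study design and treadmill training protocol.

The default design mirrors a four-group preclinical exercise study in the
SOD1-G93A mouse model of ALS: wild-type (WT) and transgenic (G93A) females,
each split into a sedentary and a treadmill-trained arm (n = 12 per group),
phenotyped twice a week from 35 to 91 days of age while the trained arms run
an 8-week, 5-days-a-week incremental endurance protocol.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

GENOTYPES = ("WT", "G93A")
ACTIVITIES = ("sedentary", "trained")

#: canonical group order: controls first, transgenics last
GROUPS: tuple[tuple[str, str], ...] = (
    ("WT", "sedentary"),
    ("WT", "trained"),
    ("G93A", "sedentary"),
    ("G93A", "trained"),
)

_ACTIVITY_ABBREV = {"sedentary": "SD", "trained": "TR"}

#: twice-weekly schedule: alternating +3/+4 day steps from day 35 to day 91
DEFAULT_MEASUREMENT_DAYS: tuple[int, ...] = (
    35, 38, 42, 45, 49, 52, 56, 59, 63, 66, 70, 73, 77, 80, 84, 87, 91,
)

DEFAULT_N_PER_GROUP = 12
DEFAULT_ENDPOINT_DAY = 91


def group_label(genotype: str, activity: str) -> str:
    """Short display label, e.g. ``('G93A', 'trained') -> 'TR-G93A'``."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype: {genotype!r}")
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity: {activity!r}")
    return f"{_ACTIVITY_ABBREV[activity]}-{genotype}"


def parse_group_label(label: str) -> tuple[str, str]:
    """Inverse of :func:`group_label`."""
    for genotype, activity in GROUPS:
        if group_label(genotype, activity) == label:
            return genotype, activity
    raise ValueError(f"unknown group label: {label!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Four-group longitudinal design with a fixed measurement grid."""

    groups: tuple[tuple[str, str], ...] = GROUPS
    n_per_group: int = DEFAULT_N_PER_GROUP
    measurement_days: tuple[int, ...] = DEFAULT_MEASUREMENT_DAYS
    endpoint_day: int = DEFAULT_ENDPOINT_DAY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        days = tuple(int(d) for d in self.measurement_days)
        if len(days) == 0:
            raise ValueError("measurement_days must be non-empty")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement_days must be strictly increasing")
        if self.endpoint_day < days[-1]:
            raise ValueError("endpoint_day must be >= last measurement day")
        for genotype, activity in self.groups:
            group_label(genotype, activity)  # validates
        object.__setattr__(self, "measurement_days", days)
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))

    @property
    def start_day(self) -> int:
        """First measurement day = training start (day 35 by default)."""
        return self.measurement_days[0]


@dataclass(frozen=True)
class TrainingSession:
    """A single treadmill session."""

    speed_m_per_min: float
    slope_deg: float
    time_min: float

    def __post_init__(self) -> None:
        # zero is allowed (a rest/sham session); negatives are not physical
        for name in ("speed_m_per_min", "slope_deg", "time_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def distance_m(self) -> float:
        return self.speed_m_per_min * self.time_min


# The intense endurance protocol: 8 weeks x 5 sessions, ramping speed,
# uphill slope and duration.  Values per week, Monday..Friday.
_SPEEDS = (
    (10, 10, 10, 10, 10),
    (10, 10, 12, 12, 12),
    (12, 12, 12, 12, 12),
    (13, 13, 13, 13, 13),
    (17, 17, 17, 17, 17),
    (19, 19, 19, 19, 19),
    (22, 22, 22, 22, 22),
    (22, 22, 22, 22, 22),
)
_SLOPES = (
    (5, 5, 10, 10, 10),
    (10, 10, 10, 10, 10),
    (10, 10, 10, 10, 10),
    (15, 15, 15, 15, 15),
    (15, 15, 15, 15, 15),
    (15, 15, 15, 15, 15),
    (15, 15, 15, 15, 15),
    (15, 15, 15, 15, 15),
)
_TIMES = (
    (15, 15, 15, 15, 15),
    (15, 15, 15, 30, 30),
    (30, 30, 30, 45, 45),
    (45, 60, 60, 60, 60),
    (60, 60, 60, 60, 60),
    (60, 60, 60, 60, 60),
    (60, 60, 60, 60, 60),
    (60, 60, 60, 60, 60),
)

N_WEEKS = 8
SESSIONS_PER_WEEK = 5


@dataclass(frozen=True)
class TrainingProtocol:
    """8-week x 5-day grid of treadmill sessions."""

    sessions: tuple[tuple[TrainingSession, ...], ...]

    def __post_init__(self) -> None:
        if len(self.sessions) != N_WEEKS or any(
            len(week) != SESSIONS_PER_WEEK for week in self.sessions
        ):
            raise ValueError(
                f"protocol must have exactly {N_WEEKS} weeks x "
                f"{SESSIONS_PER_WEEK} sessions"
            )

    @classmethod
    def default(cls) -> "TrainingProtocol":
        """The built-in incremental endurance protocol."""
        weeks = tuple(
            tuple(
                TrainingSession(float(v), float(s), float(t))
                for v, s, t in zip(_SPEEDS[w], _SLOPES[w], _TIMES[w])
            )
            for w in range(N_WEEKS)
        )
        return cls(weeks)

    def weekly_distance(self, week: int) -> float:
        """Total run distance (m) in a 1-based training week."""
        if not 1 <= week <= N_WEEKS:
            raise ValueError(f"week must be in 1..{N_WEEKS}, got {week}")
        return sum(s.distance_m for s in self.sessions[week - 1])

    def total_distance(self) -> float:
        """Cumulative training dose over the whole protocol (m)."""
        return sum(self.weekly_distance(w) for w in range(1, N_WEEKS + 1))

    def to_toml(self) -> str:
        lines: list[str] = []
        for w, week in enumerate(self.sessions, start=1):
            for d, s in enumerate(week, start=1):
                lines.append(f"[week.{w}.day.{d}]")
                lines.append(f"speed_m_per_min = {s.speed_m_per_min}")
                lines.append(f"slope_deg = {s.slope_deg}")
                lines.append(f"time_min = {s.time_min}")
                lines.append("")
        return "\n".join(lines)

    def write_toml(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml(), encoding="utf-8")

    @classmethod
    def from_toml(cls, path: str | Path) -> "TrainingProtocol":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        try:
            weeks = []
            for w in range(1, N_WEEKS + 1):
                week = []
                for d in range(1, SESSIONS_PER_WEEK + 1):
                    entry = data["week"][str(w)]["day"][str(d)]
                    week.append(
                        TrainingSession(
                            float(entry["speed_m_per_min"]),
                            float(entry["slope_deg"]),
                            float(entry["time_min"]),
                        )
                    )
                weeks.append(tuple(week))
        except KeyError as exc:
            raise ValueError(f"protocol file is missing table {exc}") from exc
        return cls(tuple(weeks))


def weekly_distance(protocol: TrainingProtocol, week: int) -> float:
    """Functional alias for :meth:`TrainingProtocol.weekly_distance`."""
    return protocol.weekly_distance(week)
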