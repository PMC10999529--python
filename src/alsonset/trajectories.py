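"""Group-level generative trajectories for the synthetic cohort.

Noise-free mean curves are piecewise linear: body weight grows linearly from
day 35 and, in transgenic groups, plateaus at a group-specific age; the two
ordinal motor rubrics (hind-limb extension reflex, gait) stay at the normal
level 5 until a group-specific decline-start age, drop to the first impaired
rubric level (4.75) on that day, and then decline linearly.  Normalized grip
strength drifts linearly (upward for trained wild types, downward for
transgenics).

Calibrated defaults encode the study landmarks: weight plateaus at 70 / 77
days (trained / sedentary G93A), reflex decline starts at 52 / 66 days and
gait decline at 59 / 70 days; trained and sedentary G93A mice lose ventral
horn motor neurons to ~50% and ~80% of the sedentary-WT level by day 91.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from typing import Mapping, Optional

from .design import GROUPS, StudyDesign, group_label

#: ordinal rubric levels, best (normal) to worst (humane endpoint)
RUBRIC_LEVELS: tuple[float, ...] = (
    5.0, 4.75, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5,
)

#: first level below "normal function"; where a decline becomes visible
FIRST_IMPAIRED_LEVEL = 4.75

#: rubric floor used by the latent curve (humane-endpoint level)
SCORE_FLOOR = 0.5

MOTOR_TESTS = ("reflex", "gait")


@dataclass(frozen=True)
class GroupTrajectory:
    """Generative parameters for one genotype x activity group.

    Weight in grams, ages in days, grip in arbitrary normalized units
    (force per gram of body weight), rubric scores on the 5..0.5 scale.
    """

    weight_start_mean: float = 17.0
    weight_start_sd: float = 1.0
    weight_growth_rate: float = 0.10  # g/day
    weight_plateau_day: Optional[int] = None
    weight_noise_sd: float = 0.4
    grip_start_mean: float = 5.0
    grip_start_sd: float = 0.25
    grip_slope: float = 0.0  # normalized grip units/day
    grip_noise_sd: float = 0.10  # per attempt
    reflex_decline_start: Optional[int] = None
    gait_decline_start: Optional[int] = None
    motor_decline_rate: float = 0.05  # score units/day
    observer_flip_prob: float = 0.10
    endpoint_mn_mean: float = 100.0  # % motor neurons vs sedentary WT
    endpoint_mn_sd: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "weight_start_sd", "weight_noise_sd", "grip_start_sd",
            "grip_noise_sd", "endpoint_mn_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motor_decline_rate <= 0:
            raise ValueError("motor_decline_rate must be > 0")
        if not 0.0 <= self.observer_flip_prob <= 0.5:
            raise ValueError("observer_flip_prob must be in [0, 0.5]")
        if self.weight_start_mean <= 0:
            raise ValueError("weight_start_mean must be > 0")
        if self.endpoint_mn_mean <= 0:
            raise ValueError("endpoint_mn_mean must be > 0")

    def decline_start(self, test: str) -> Optional[int]:
        if test == "reflex":
            return self.reflex_decline_start
        if test == "gait":
            return self.gait_decline_start
        raise ValueError(f"unknown motor test: {test!r}")

    def without_noise(self) -> "GroupTrajectory":
        """Copy with every stochastic term switched off."""
        return replace(
            self,
            weight_start_sd=0.0,
            weight_noise_sd=0.0,
            grip_start_sd=0.0,
            grip_noise_sd=0.0,
            observer_flip_prob=0.0,
            endpoint_mn_sd=0.0,
        )


@dataclass(frozen=True)
class TrajectoryParams:
    """Per-group generative parameters keyed by (genotype, activity)."""

    groups: Mapping[tuple[str, str], GroupTrajectory]

    def __post_init__(self) -> None:
        validated = {}
        for key, traj in dict(self.groups).items():
            genotype, activity = key
            group_label(genotype, activity)  # validates the key
            if not isinstance(traj, GroupTrajectory):
                raise TypeError("group entries must be GroupTrajectory")
            validated[(genotype, activity)] = traj
        object.__setattr__(self, "groups", validated)

    def __getitem__(self, key: tuple[str, str]) -> GroupTrajectory:
        try:
            return self.groups[key]
        except KeyError:
            raise KeyError(f"no trajectory parameters for group {key!r}") from None

    def without_noise(self) -> "TrajectoryParams":
        return TrajectoryParams(
            {k: t.without_noise() for k, t in self.groups.items()}
        )

    def validate_against(self, design: StudyDesign) -> None:
        """Check that every breakpoint lies inside the measurement window."""
        lo, hi = design.measurement_days[0], design.measurement_days[-1]
        for key in design.groups:
            traj = self[tuple(key)]
            for name in ("weight_plateau_day", "reflex_decline_start",
                         "gait_decline_start"):
                day = getattr(traj, name)
                if day is not None and not lo <= day <= hi:
                    raise ValueError(
                        f"{name}={day} for group {key} outside the "
                        f"measurement window [{lo}, {hi}]"
                    )


def default_params() -> TrajectoryParams:
    """Calibrated default parameters for the four study groups."""
    return TrajectoryParams(
        {
            ("WT", "sedentary"): GroupTrajectory(),
            ("WT", "trained"): GroupTrajectory(
                grip_slope=0.010,  # training improves WT strength
            ),
            ("G93A", "sedentary"): GroupTrajectory(
                weight_plateau_day=77,
                grip_slope=-0.028,
                reflex_decline_start=66,
                gait_decline_start=70,
                endpoint_mn_mean=80.0,
                endpoint_mn_sd=8.0,
            ),
            ("G93A", "trained"): GroupTrajectory(
                weight_plateau_day=70,
                grip_slope=-0.038,
                reflex_decline_start=52,
                gait_decline_start=59,
                endpoint_mn_mean=50.0,
                endpoint_mn_sd=5.0,
            ),
        }
    )


def mean_weight_curve(
    params: TrajectoryParams,
    group: tuple[str, str],
    day: float,
    start_day: int = 35,
) -> float:
    """Noise-free mean body weight (g) at a given age.

    Linear growth from ``start_day``; constant after the group's plateau day
    (if any), so the curve is monotone nondecreasing.
    """
    traj = params[group]
    effective_day = day
    if traj.weight_plateau_day is not None:
        effective_day = min(day, traj.weight_plateau_day)
    return traj.weight_start_mean + traj.weight_growth_rate * (
        effective_day - start_day
    )


def mean_grip_curve(
    params: TrajectoryParams,
    group: tuple[str, str],
    day: float,
    start_day: int = 35,
) -> float:
    """Noise-free mean normalized grip strength at a given age."""
    traj = params[group]
    return max(0.0, traj.grip_start_mean + traj.grip_slope * (day - start_day))


def latent_motor_curve(
    params: TrajectoryParams,
    group: tuple[str, str],
    day: float,
    test: str = "reflex",
) -> float:
    """Noise-free latent motor score at a given age.

    Equals 5 before the group's decline-start day (always 5 if no decline is
    configured).  On the decline-start day the score has dropped to the first
    impaired rubric level (4.75) -- the first sub-normal observation lands
    exactly on the reported decline age -- and it then falls linearly at
    ``motor_decline_rate``, floored at the humane-endpoint level 0.5.
    """
    traj = params[group]
    start = traj.decline_start(test)
    if start is None or day < start:
        return 5.0
    value = FIRST_IMPAIRED_LEVEL - traj.motor_decline_rate * (day - start)
    return max(SCORE_FLOOR, value)


def discretize_score(latent: float) -> float:
    """Map a latent score in [0, 5] to the nearest rubric level.

    Ties round down, toward the worse score.
    """
    if not 0.0 <= latent <= 5.0:
        raise ValueError(f"latent score {latent} outside [0, 5]")
    best = RUBRIC_LEVELS[0]
    best_dist = abs(latent - best)
    for level in RUBRIC_LEVELS[1:]:
        dist = abs(latent - level)
        if dist <= best_dist:  # <= : ties go to the lower level
            best, best_dist = level, dist
    return best
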