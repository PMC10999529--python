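"""Seeded synthetic-cohort generator.

Produces a longitudinal phenotype table (one row per mouse x measurement day:
weight, three grip attempts, reflex and gait rubric scores) and an endpoint
table (per-mouse ventral-horn motor-neuron percentage) from group-level
trajectory parameters.  Same seed, same tables, bit for bit; with every noise
term at zero the emitted values equal the analytic mean curves (motor scores:
their rubric discretization).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import StudyDesign, TrainingProtocol, group_label
from .trajectories import (
    RUBRIC_LEVELS,
    TrajectoryParams,
    discretize_score,
    latent_motor_curve,
    mean_grip_curve,
    mean_weight_curve,
)

LONGITUDINAL_COLUMNS = (
    "mouse_id", "genotype", "activity", "day",
    "weight_g", "grip1", "grip2", "grip3", "reflex_score", "gait_score",
)
ENDPOINT_COLUMNS = ("mouse_id", "genotype", "activity", "mn_pct")

_LEVELS = np.asarray(RUBRIC_LEVELS)  # descending


def _observer_flip(
    score_idx: np.ndarray, flip_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply +-1 rubric-level observer error with the given probability.

    Index arithmetic on the descending level list; flips past either end of
    the scale clamp back onto it.
    """
    u = rng.random(score_idx.shape)
    direction = np.where(rng.random(score_idx.shape) < 0.5, -1, 1)
    flipped = np.where(u < flip_prob, score_idx + direction, score_idx)
    return np.clip(flipped, 0, len(_LEVELS) - 1)


def simulate_cohort(
    design: StudyDesign | None = None,
    params: TrajectoryParams | None = None,
    protocol: TrainingProtocol | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns ``(longitudinal, endpoint)`` tables.

    Parameters
    ----------
    design
        Group structure and measurement schedule (study defaults if omitted).
    params
        Per-group trajectory parameters (calibrated defaults if omitted).
    protocol
        Training protocol; carried for provenance/dose reporting only -- the
        group trajectories already encode its phenotypic consequences.
    seed
        RNG seed.  Falls back to ``design.seed``; must not be None.
    """
    from .trajectories import default_params  # avoid cycle at import time

    if design is None:
        design = StudyDesign()
    if params is None:
        params = default_params()
    if seed is None:
        seed = design.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    params.validate_against(design)

    rng = np.random.default_rng(int(seed))
    days = np.asarray(design.measurement_days, dtype=float)
    n_days = len(days)
    n = design.n_per_group
    start_day = design.start_day

    long_parts: list[pd.DataFrame] = []
    end_parts: list[pd.DataFrame] = []

    for genotype, activity in design.groups:
        traj = params[(genotype, activity)]
        label = group_label(genotype, activity)
        mouse_ids = [f"{label}-{i + 1:02d}" for i in range(n)]

        weight_start = rng.normal(traj.weight_start_mean, traj.weight_start_sd, n)
        grip_start = rng.normal(traj.grip_start_mean, traj.grip_start_sd, n)

        # analytic mean curves on the schedule
        w_mean = np.array(
            [mean_weight_curve(params, (genotype, activity), d, start_day)
             for d in days]
        )
        g_mean = np.array(
            [mean_grip_curve(params, (genotype, activity), d, start_day)
             for d in days]
        )
        # per-mouse offsets shift the whole trajectory; measurement noise is
        # drawn independently per day
        w = (
            w_mean[None, :]
            + (weight_start - traj.weight_start_mean)[:, None]
            + rng.normal(0.0, traj.weight_noise_sd, (n, n_days))
        )
        w = np.maximum(w, 0.1)

        g_latent = g_mean[None, :] + (grip_start - traj.grip_start_mean)[:, None]
        attempts = (
            g_latent[:, :, None]
            + rng.normal(0.0, traj.grip_noise_sd, (n, n_days, 3))
        ) * w[:, :, None]
        attempts = np.maximum(attempts, 0.0)

        scores: dict[str, np.ndarray] = {}
        for test in ("reflex", "gait"):
            latent = np.array(
                [latent_motor_curve(params, (genotype, activity), d, test)
                 for d in days]
            )
            idx_1d = np.array(
                [int(np.argmin(np.abs(_LEVELS - discretize_score(v))))
                 for v in latent]
            )
            idx = np.broadcast_to(idx_1d, (n, n_days)).copy()
            if traj.observer_flip_prob > 0:
                idx = _observer_flip(idx, traj.observer_flip_prob, rng)
            scores[test] = _LEVELS[idx]

        mn = rng.normal(traj.endpoint_mn_mean, traj.endpoint_mn_sd, n)
        mn = np.maximum(mn, 0.1)

        long_parts.append(
            pd.DataFrame(
                {
                    "mouse_id": np.repeat(mouse_ids, n_days),
                    "genotype": genotype,
                    "activity": activity,
                    "day": np.tile(design.measurement_days, n),
                    "weight_g": w.ravel(),
                    "grip1": attempts[:, :, 0].ravel(),
                    "grip2": attempts[:, :, 1].ravel(),
                    "grip3": attempts[:, :, 2].ravel(),
                    "reflex_score": scores["reflex"].ravel(),
                    "gait_score": scores["gait"].ravel(),
                }
            )
        )
        end_parts.append(
            pd.DataFrame(
                {
                    "mouse_id": mouse_ids,
                    "genotype": genotype,
                    "activity": activity,
                    "mn_pct": mn,
                }
            )
        )

    longitudinal = pd.concat(long_parts, ignore_index=True)
    endpoint = pd.concat(end_parts, ignore_index=True)
    return longitudinal, endpoint
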