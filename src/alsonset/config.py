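"""Pipeline configuration (TOML) and run manifests.

The config file round-trips losslessly: :meth:`PipelineConfig.to_toml`
writes every field explicitly and :meth:`PipelineConfig.from_toml` rejects
unknown keys, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

from .design import (
    DEFAULT_ENDPOINT_DAY,
    DEFAULT_MEASUREMENT_DAYS,
    DEFAULT_N_PER_GROUP,
    GROUPS,
    StudyDesign,
    group_label,
    parse_group_label,
)
from .scoring import DEFAULT_THRESHOLD, ReferencePolicy
from .trajectories import GroupTrajectory, TrajectoryParams, default_params

_OPTIONAL_DAY_FIELDS = {
    "weight_plateau_day", "reflex_decline_start", "gait_decline_start",
}


@dataclass(frozen=True)
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    params: TrajectoryParams = field(default_factory=default_params)
    policy: ReferencePolicy = field(default_factory=ReferencePolicy)
    threshold: float = DEFAULT_THRESHOLD
    persistence: int = 1
    output_dir: str = "results"

    # ---- TOML serialization -------------------------------------------------

    def to_toml(self) -> str:
        d = self.design
        lines = [
            "[design]",
            f"n_per_group = {d.n_per_group}",
            f"measurement_days = {list(d.measurement_days)}",
            f"endpoint_day = {d.endpoint_day}",
            f"seed = {d.seed}",
            "",
            "[scoring]",
            f"threshold = {_toml_value(float(self.threshold))}",
            f"persistence = {self.persistence}",
            f'weight_reference = "{self.policy.weight_ref}"',
            f'grip_reference = "{self.policy.grip_ref}"',
            f"latch = {str(self.policy.latch).lower()}",
            "",
            "[output]",
            f'dir = "{self.output_dir}"',
            "",
        ]
        for genotype, activity in GROUPS:
            if (genotype, activity) not in self.params.groups:
                continue
            traj = self.params[(genotype, activity)]
            lines.append(f'[trajectories."{group_label(genotype, activity)}"]')
            for f_ in fields(GroupTrajectory):
                value = getattr(traj, f_.name)
                if value is None:
                    value = "none"  # TOML has no null; "none" = no breakpoint
                lines.append(f"{f_.name} = {_toml_value(value)}")
            lines.append("")
        return "\n".join(lines)

    def write_toml(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml(), encoding="utf-8")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        allowed_sections = {"design", "scoring", "output", "trajectories"}
        unknown = set(data) - allowed_sections
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")

        design_raw = dict(data.get("design", {}))
        _reject_unknown(design_raw, {"n_per_group", "measurement_days",
                                     "endpoint_day", "seed"}, "design")
        design = StudyDesign(
            n_per_group=int(design_raw.get("n_per_group", DEFAULT_N_PER_GROUP)),
            measurement_days=tuple(
                design_raw.get("measurement_days", DEFAULT_MEASUREMENT_DAYS)
            ),
            endpoint_day=int(design_raw.get("endpoint_day", DEFAULT_ENDPOINT_DAY)),
            seed=int(design_raw.get("seed", 0)),
        )

        scoring_raw = dict(data.get("scoring", {}))
        _reject_unknown(
            scoring_raw,
            {"threshold", "persistence", "weight_reference",
             "grip_reference", "latch"},
            "scoring",
        )
        policy = ReferencePolicy(
            weight_ref=scoring_raw.get("weight_reference", "sedentary_wt"),
            grip_ref=scoring_raw.get("grip_reference", "running_max"),
            latch=bool(scoring_raw.get("latch", False)),
        )

        output_raw = dict(data.get("output", {}))
        _reject_unknown(output_raw, {"dir"}, "output")

        base = default_params()
        traj_raw = dict(data.get("trajectories", {}))
        groups = dict(base.groups)
        valid_fields = {f_.name for f_ in fields(GroupTrajectory)}
        for label, overrides in traj_raw.items():
            key = parse_group_label(label)
            _reject_unknown(dict(overrides), valid_fields,
                            f"trajectories.{label}")
            merged: dict[str, Any] = dataclasses.asdict(groups[key])
            for name, value in dict(overrides).items():
                if name in _OPTIONAL_DAY_FIELDS and value == "none":
                    value = None
                merged[name] = value
            groups[key] = GroupTrajectory(**merged)
        params = TrajectoryParams(groups)

        return cls(
            design=design,
            params=params,
            policy=policy,
            threshold=float(scoring_raw.get("threshold", DEFAULT_THRESHOLD)),
            persistence=int(scoring_raw.get("persistence", 1)),
            output_dir=str(output_raw.get("dir", "results")),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode("utf-8")).hexdigest()


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, int):
        return str(value)
    return f'"{value}"'


def _reject_unknown(raw: dict, allowed: set[str], section: str) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")


@dataclass
class RunManifest:
    """Provenance record written next to every stage's outputs."""

    stage: str
    seed: int
    config_hash: str
    package_version: str
    elapsed_s: float
    outputs: list[str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n",
                        encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
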