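"""CSV readers/writers with schema validation.

All tables are plain comma-separated UTF-8 with a header row and '.' decimal
separator.  Readers fail loudly, naming the first missing column, so that a
malformed lab export cannot silently flow through the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trajectories import RUBRIC_LEVELS

LONGITUDINAL_SCHEMA = (
    "mouse_id", "genotype", "activity", "day",
    "weight_g", "grip1", "grip2", "grip3", "reflex_score", "gait_score",
)
ENDPOINT_SCHEMA = ("mouse_id", "genotype", "activity", "mn_pct")
SCORES_SCHEMA = (
    "mouse_id", "genotype", "activity", "day", "norm_grip",
    "weight_ref", "grip_ref", "i_weight", "i_grip", "i_reflex", "i_gait",
    "total",
)
ONSET_SCHEMA = ("mouse_id", "genotype", "activity", "event", "time_days")


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, schema: tuple[str, ...], what: str) -> None:
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing column {col!r}")


def _check_rubric_column(df: pd.DataFrame, col: str, what: str) -> None:
    levels = np.asarray(RUBRIC_LEVELS)
    values = df[col].to_numpy(dtype=float)
    ok = np.isclose(values[:, None], levels[None, :], atol=1e-9).any(axis=1)
    if not ok.all():
        bad = values[~ok][0]
        raise SchemaError(
            f"{what} table column {col!r} contains value {bad!r} outside the "
            f"rubric level set {RUBRIC_LEVELS}"
        )


def read_longitudinal(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, LONGITUDINAL_SCHEMA, "longitudinal")
    for col in ("reflex_score", "gait_score"):
        _check_rubric_column(df, col, "longitudinal")
    if (df["weight_g"].to_numpy(dtype=float) <= 0).any():
        raise SchemaError("longitudinal table has nonpositive weight_g values")
    if df.duplicated(["mouse_id", "day"]).any():
        raise SchemaError("longitudinal table has duplicate mouse_id x day rows")
    return df


def read_endpoint(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ENDPOINT_SCHEMA, "endpoint")
    if (df["mn_pct"].to_numpy(dtype=float) <= 0).any():
        raise SchemaError("endpoint table has nonpositive mn_pct values")
    if df["mouse_id"].duplicated().any():
        raise SchemaError("endpoint table has duplicate mouse_id rows")
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SCORES_SCHEMA, "score")
    return df


def read_onsets(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ONSET_SCHEMA, "onset")
    if not df["event"].isin((0, 1)).all():
        raise SchemaError("onset table column 'event' must be 0/1")
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
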