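"""Trial-table and configuration I/O.

The canonical on-disk trial format is CSV (comma separated, UTF-8, header
row, floats at 6 significant digits); TSV is accepted on read.  The
column set is the one produced by :mod:`popmem.experiments`.  Reading
validates the schema and the stimulus ranges and reports the first
offending row and field, so malformed tables fail loudly rather than
propagate.

Run configuration is a strict-keyed mapping loadable from YAML or JSON;
unknown keys are rejected, not ignored, and every stochastic run records
its master seed in its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .experiments import COLUMNS, EMOTIONS

__all__ = [
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "RunConfig",
]

FLOAT_FORMAT = "%.6g"


class TrialValidationError(ValueError):
    """A trial table failed schema or range validation."""

    def __init__(self, message: str, row: Optional[int] = None, column: Optional[str] = None):
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {column!r})" if column else ")")
        super().__init__(message + loc)
        self.row = row
        self.column = column


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as canonical CSV."""
    trials.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _first_bad(mask: np.ndarray) -> int:
    return int(np.flatnonzero(mask)[0])


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table (CSV; TSV accepted).

    An empty file with a valid header yields an empty table.  Out-of-range
    targets or responses (faces outside [0, 100], gratings outside
    [0, 180)) raise :class:`TrialValidationError` naming row and field.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if sep not in header and "\t" in header:
        sep = "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")
    df = df[COLUMNS].copy()
    if len(df) == 0:
        return df
    df["probed"] = df["probed"].astype(bool)
    kind = df["item_kind"].to_numpy()
    bad_kind = ~np.isin(kind, ["face", "grating"])
    if bad_kind.any():
        r = _first_bad(bad_kind)
        raise TrialValidationError(
            f"item_kind must be 'face' or 'grating', got {kind[r]!r}", r, "item_kind"
        )
    for col in ("target", "response"):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        present = ~pd.isna(df[col]).to_numpy()
        is_face = kind == "face"
        bad = present & is_face & ((vals < 0.0) | (vals > 100.0))
        if bad.any():
            r = _first_bad(bad)
            raise TrialValidationError(
                f"face {col} outside [0, 100]: {vals[r]!r}", r, col
            )
        bad = present & ~is_face & ((vals < 0.0) | (vals >= 180.0))
        if bad.any():
            r = _first_bad(bad)
            raise TrialValidationError(
                f"grating {col} outside [0, 180): {vals[r]!r}", r, col
            )
    face_emos = df.loc[(kind == "face"), "emotion"]
    bad_emo = ~face_emos.isin(EMOTIONS)
    if bad_emo.any():
        r = int(face_emos.index[bad_emo][0])
        raise TrialValidationError(
            f"unknown emotion {face_emos[bad_emo].iloc[0]!r}", r, "emotion"
        )
    return df


_VALID_TASKS = ("orientation_ml", "orientation_sampling", "expression_sampling")


@dataclass
class RunConfig:
    """Strict-keyed run configuration for the pipeline commands."""

    experiment: str = "1A"
    task: str = "expression_sampling"
    decoder: Optional[str] = None
    n_participants: int = 1
    n_sim: Optional[int] = None
    n_bins: Optional[int] = None
    seed: int = 0
    grids: str = "task-default"
    gain_grid: Optional[Sequence[float]] = None
    width_grid: Optional[Sequence[float]] = None
    grouping: Sequence[str] = field(default_factory=lambda: ["participant", "emotion"])
    model: dict = field(default_factory=dict)
    input: Optional[str] = None
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in ("1A", "1B", "1C"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.task not in _VALID_TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {_VALID_TASKS}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
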