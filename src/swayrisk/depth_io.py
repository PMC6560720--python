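"""On-disk formats for depth sequences and cohort tables.

A depth sequence is a directory of 16-bit grayscale PNG frames
(``frame_%06d.png``) plus a ``meta.json`` carrying the frame rate, depth
scale, pinhole intrinsics and the number of leading person-free
(background) frames.  Stored pixel values times ``depth_scale_mm`` give
depth in millimetres; 0 is reserved for invalid / no-return pixels.

A cohort table is a UTF-8 CSV (comma separator, decimal point) with one
row per participant: demographics, weekly activity volume, three Timed Up
and Go trial times, and optionally per-task/per-trial balance parameters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "DepthFrame",
    "DepthSequence",
    "CohortTable",
    "DepthFormatError",
    "CohortFormatError",
    "read_depth_sequence",
    "write_depth_sequence",
    "read_cohort",
    "write_cohort",
    "PARAMETER_NAMES",
    "feature_column",
]

META_NAME = "meta.json"
FRAME_PATTERN = re.compile(r"^frame_(\d{6})\.png$")

#: Canonical order of the three balance parameters.
PARAMETER_NAMES = ("centroid_variability", "centroid_max_speed", "max_dispersion")

#: Column stubs used in the cohort CSV for each parameter.
_PARAM_STUBS = {
    "centroid_variability": "centroid_var",
    "centroid_max_speed": "centroid_max_speed",
    "max_dispersion": "max_dispersion",
}


class DepthFormatError(ValueError):
    """A depth-sequence directory violates the on-disk format."""


class CohortFormatError(ValueError):
    """A cohort CSV violates the format contract."""


def feature_column(task: int, trial: int, parameter: str) -> str:
    """CSV column name for one (task, trial, parameter) feature value."""
    return f"task{task}_trial{trial}_{_PARAM_STUBS[parameter]}"


@dataclass(frozen=True)
class DepthFrame:
    """One depth image: integer millimetre-unit grid, 0 = invalid pixel."""

    grid: np.ndarray
    index: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("depth grid must be 2-D")
        if np.any(grid < 0):
            raise ValueError("depth values must be non-negative")
        object.__setattr__(self, "grid", grid)

    def depth_mm(self, depth_scale_mm: float = 1.0) -> np.ndarray:
        """Depth in millimetres as float, NaN where invalid (0)."""
        d = self.grid.astype(float) * depth_scale_mm
        d[self.grid == 0] = np.nan
        return d


@dataclass
class DepthSequence:
    """Ordered stack of depth frames with camera metadata.

    ``intrinsics`` is the pinhole tuple (fx, fy, cx, cy) in pixels;
    ``background_frames`` counts leading frames guaranteed person-free.
    Timestamps are implicit: frame ``i`` occurs at ``i / frame_rate_hz``.
    """

    frames: list[DepthFrame]
    frame_rate_hz: float = 30.0
    depth_scale_mm: float = 1.0
    intrinsics: tuple[float, float, float, float] = (365.456, 365.456, 256.0, 212.0)
    background_frames: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a depth sequence needs at least one frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.depth_scale_mm <= 0:
            raise ValueError("depth_scale_mm must be positive")
        if not 0 <= self.background_frames < len(self.frames):
            raise ValueError("background_frames must be < number of frames")
        shape = self.frames[0].grid.shape
        for f in self.frames:
            if f.grid.shape != shape:
                raise ValueError("frame dimensions must be constant")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].grid.shape

    def __len__(self) -> int:
        return len(self.frames)

    def person_frames(self) -> list[DepthFrame]:
        """Frames after the leading background block."""
        return self.frames[self.background_frames :]


def write_depth_sequence(seq: DepthSequence, path: str | Path) -> Path:
    """Write a sequence as ``meta.json`` + 16-bit PNGs; returns the directory."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    fx, fy, cx, cy = seq.intrinsics
    meta = {
        "frame_rate_hz": seq.frame_rate_hz,
        "depth_scale_mm": seq.depth_scale_mm,
        "fx": fx,
        "fy": fy,
        "cx": cx,
        "cy": cy,
        "background_frames": seq.background_frames,
    }
    (out / META_NAME).write_text(json.dumps(meta, indent=2, sort_keys=True))
    for i, frame in enumerate(seq.frames):
        grid = np.asarray(frame.grid)
        if grid.max(initial=0) > np.iinfo(np.uint16).max:
            raise DepthFormatError("depth value exceeds 16-bit range")
        iio.imwrite(out / f"frame_{i:06d}.png", grid.astype(np.uint16))
    return out


def read_depth_sequence(path: str | Path) -> DepthSequence:
    """Read a depth-sequence directory written by :func:`write_depth_sequence`."""
    root = Path(path)
    meta_path = root / META_NAME
    if not meta_path.is_file():
        raise DepthFormatError(f"missing {META_NAME} in {root}")
    meta = json.loads(meta_path.read_text())
    try:
        intrinsics = (meta["fx"], meta["fy"], meta["cx"], meta["cy"])
        rate = float(meta["frame_rate_hz"])
        scale = float(meta["depth_scale_mm"])
        background = int(meta["background_frames"])
    except KeyError as exc:
        raise DepthFormatError(f"meta.json missing key {exc}") from exc

    indexed = []
    for p in root.iterdir():
        m = FRAME_PATTERN.match(p.name)
        if m:
            indexed.append((int(m.group(1)), p))
    if not indexed:
        raise DepthFormatError(f"no frame_<index>.png files in {root}")
    indexed.sort()

    frames: list[DepthFrame] = []
    shape = None
    for index, p in indexed:
        grid = iio.imread(p)
        if grid.dtype != np.uint16:
            raise DepthFormatError(f"{p.name}: expected 16-bit grayscale, got {grid.dtype}")
        if shape is None:
            shape = grid.shape
        elif grid.shape != shape:
            raise DepthFormatError(f"{p.name}: frame dimensions differ from first frame")
        frames.append(DepthFrame(grid=grid, index=index))
    return DepthSequence(
        frames=frames,
        frame_rate_hz=rate,
        depth_scale_mm=scale,
        intrinsics=tuple(float(v) for v in intrinsics),
        background_frames=background,
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["id", "group", "age", "activity_met_min_week", "tug_1", "tug_2", "tug_3"]
_GROUPS = {"young", "elderly"}


@dataclass
class CohortTable:
    """Participants x (demographics, activity, TUG trials, balance features).

    Thin wrapper around a pandas DataFrame with one row per participant.
    Feature columns follow :func:`feature_column` naming; any other columns
    are carried through reads and writes untouched.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _BASE_COLUMNS if c not in df.columns]
        if missing:
            raise CohortFormatError(f"cohort table missing columns: {missing}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise CohortFormatError(f"duplicate participant ids: {dupes}")
        bad_group = set(df["group"]) - _GROUPS
        if bad_group:
            raise CohortFormatError(f"unknown group labels: {sorted(bad_group)}")
        tug = df[["tug_1", "tug_2", "tug_3"]].to_numpy(dtype=float)
        if not np.all(tug > 0):
            raise CohortFormatError("TUG trial times must be positive")
        if not np.all(df["activity_met_min_week"].to_numpy(dtype=float) >= 0):
            raise CohortFormatError("activity must be non-negative")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].astype(str).tolist()

    def ids_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "id"].astype(str).tolist()

    @property
    def young_ids(self) -> list[str]:
        return self.ids_in_group("young")

    @property
    def elderly_ids(self) -> list[str]:
        return self.ids_in_group("elderly")

    def tasks_present(self) -> list[int]:
        """Task numbers for which both trials of all three parameters exist."""
        tasks = []
        for task in range(1, 65):
            cols = [
                feature_column(task, trial, p)
                for trial in (1, 2)
                for p in PARAMETER_NAMES
            ]
            if all(c in self.table.columns for c in cols):
                tasks.append(task)
        return tasks

    def trial_features(self, task: int, trial: int) -> pd.DataFrame:
        """One trial's three parameters, indexed by participant id."""
        cols = {feature_column(task, trial, p): p for p in PARAMETER_NAMES}
        missing = [c for c in cols if c not in self.table.columns]
        if missing:
            raise CohortFormatError(f"missing feature columns: {missing}")
        out = self.table[["id", *cols]].rename(columns=cols)
        return out.set_index("id")

    def task_features(self, task: int, parameters: Sequence[str] = PARAMETER_NAMES) -> pd.DataFrame:
        """Trial-averaged parameters for one task, participants x parameters."""
        t1 = self.trial_features(task, 1)[list(parameters)]
        t2 = self.trial_features(task, 2)[list(parameters)]
        return (t1 + t2) / 2.0

    def tug_performance(self) -> pd.Series:
        """Mean of TUG trials 2 and 3 (trial 1 is familiarization), by id."""
        df = self.table
        return pd.Series(
            (df["tug_2"].to_numpy(float) + df["tug_3"].to_numpy(float)) / 2.0,
            index=df["id"].astype(str),
            name="tug",
        )

    def variable(self, name: str) -> pd.Series:
        """Evaluation variable by id: 'age', 'activity' or 'tug'."""
        if name == "tug":
            return self.tug_performance()
        column = {"age": "age", "activity": "activity_met_min_week"}.get(name)
        if column is None:
            raise KeyError(f"unknown variable {name!r}")
        df = self.table
        return pd.Series(df[column].to_numpy(float), index=df["id"].astype(str), name=name)

    def with_features(self, rows: pd.DataFrame) -> "CohortTable":
        """Return a copy with feature columns joined/overwritten by id."""
        merged = self.table.set_index("id")
        for col in rows.columns:
            merged[col] = rows[col]
        return CohortTable(merged.reset_index())


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    ordered = _BASE_COLUMNS + [c for c in cohort.table.columns if c not in _BASE_COLUMNS]
    cohort.table[ordered].to_csv(out, index=False)
    return out


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"id": str, "group": str})
    return CohortTable(df)
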