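"""Image-stack and track-table I/O, acquisition metadata, and report writing.

Conventions used throughout the package:

* coordinates are in **pixels**, origin at the center of the top-left pixel,
  x rightward, y downward (image convention); frames are 0-based;
* all unit conversion (pixels to micrometers, frames to minutes) happens in
  the kinematics layer via :class:`AcquisitionConfig`;
* reports are CSV, one per-cell table and one population table, with a fixed
  column order so downstream parsing is trivial to audit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted as the expected format."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks required columns."""


class IntegrityError(ValueError):
    """Raised when a tabular input violates uniqueness constraints."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition metadata needed to convert pixel/frame units to µm/min.

    Parameters
    ----------
    pixel_size_um : float
        Physical side of one pixel in micrometers (default 1.314, typical of a
        widefield 10x objective with 2x2 binning).
    frame_interval_min : float
        Minutes between consecutive frames (default 7).
    interval_size : int
        Frame-binning interval ``a``: kinematic quantities are computed between
        frames ``n`` and ``n + a`` with ``n`` sliding by 1 (overlapping
        intervals). Default 3, which suppresses sub-cellular positional jitter
        without discarding time resolution.
    """

    pixel_size_um: float = 1.314
    frame_interval_min: float = 7.0
    interval_size: int = 3

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0 and np.isfinite(self.pixel_size_um)):
            raise ValueError("pixel_size_um must be a positive finite number")
        if not (self.frame_interval_min > 0 and np.isfinite(self.frame_interval_min)):
            raise ValueError("frame_interval_min must be a positive finite number")
        if int(self.interval_size) != self.interval_size or self.interval_size < 1:
            raise ValueError("interval_size must be an integer >= 1")


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of same-sized grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width), non-negative intensities
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise FormatError(
                f"expected a (frames, height, width) array, got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise FormatError("a stack needs at least 2 frames")
        if not np.isfinite(frames).all():
            raise FormatError("frame intensities must be finite")
        if (frames < 0).any():
            raise FormatError("frame intensities must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class Track:
    """One cell's ordered positions: rows of (frame_index, x_px, y_px).

    Frame indices are strictly increasing; gaps are allowed (e.g. when the
    linker skipped a missed detection) and downstream code uses actual frame
    differences rather than assuming contiguity.
    """

    cell_id: int
    points: np.ndarray  # (L, 3) float: frame, x, y

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (L, 3) array of (frame, x, y)")
        if pts.shape[0] < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.isfinite(pts).all():
            raise ValueError("track coordinates must be finite")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def frames(self) -> np.ndarray:
        return self.points[:, 0].astype(int)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, 1:3]


def read_stack(path: str | os.PathLike, config: AcquisitionConfig) -> FrameStack:
    """Read a multi-page TIFF or an AVI into a :class:`FrameStack`.

    Intensities are kept at their stored bit depth without rescaling. AVI
    decoding requires an imageio video plugin (ffmpeg or pyav); without one,
    AVI input raises :class:`FormatError`. Color frames are converted to
    grayscale by channel averaging with a warning, since detection operates on
    a single intensity channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - wrap any reader failure
            raise FormatError(f"could not read TIFF stack {path}: {exc}") from exc
    elif suffix == ".avi":
        frames = _read_avi(path)
    else:
        raise FormatError(f"unsupported stack container {suffix!r} (use TIFF or AVI)")
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise FormatError(f"{path} contains a single frame; a stack needs >= 2")
    if frames.ndim == 4:  # (frames, h, w, channels) -> grayscale
        import warnings

        warnings.warn(
            f"{path.name}: color frames averaged to grayscale", stacklevel=2
        )
        frames = frames.mean(axis=-1)
    if frames.ndim != 3:
        raise FormatError(f"unexpected stack dimensionality {frames.shape} in {path}")
    return FrameStack(frames=frames.astype(float), config=config)


def _read_avi(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, index=None)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(
            f"could not decode AVI {path}: {exc} "
            "(an imageio video plugin such as ffmpeg or pyav is required)"
        ) from exc
    return np.asarray(frames)


TRACK_COLUMNS = ("cell_id", "frame", "x", "y")


def read_tracks_csv(path: str | os.PathLike) -> list[Track]:
    """Read a track table CSV with columns cell_id, frame, x, y into Tracks.

    Rows may appear in any order; points are sorted by frame within each cell.
    Duplicate (cell_id, frame) rows raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track CSV {path} lacks column(s) {missing}")
    if df.empty:
        raise FormatError(f"track CSV {path} has no rows")
    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        first = df.loc[dup, ["cell_id", "frame"]].iloc[0]
        raise IntegrityError(
            f"duplicate (cell_id, frame) = ({first.cell_id}, {first.frame}) in {path}"
        )
    tracks = []
    for cell_id, grp in df.sort_values(["cell_id", "frame"]).groupby("cell_id", sort=True):
        pts = grp[["frame", "x", "y"]].to_numpy(dtype=float)
        tracks.append(Track(cell_id=int(cell_id), points=pts))
    return tracks


def write_tracks_csv(tracks: Iterable[Track], path: str | os.PathLike) -> Path:
    """Write tracks to a CSV with columns cell_id, frame, x, y."""
    path = Path(path)
    rows = []
    for t in tracks:
        for frame, x, y in t.points:
            rows.append((t.cell_id, int(frame), x, y))
    df = pd.DataFrame(rows, columns=list(TRACK_COLUMNS))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


PER_CELL_COLUMNS = (
    "cell_id",
    "frame",
    "x",
    "y",
    "displacement_px",
    "theta_trajectory_deg",
    "theta_deflection_deg",
    "msd_px2",
)

POPULATION_COLUMNS = (
    "frame",
    "avg_displacement_px",
    "avg_theta_trajectory_deg",
    "pct_turning_gt_90",
    "avg_abs_deflection_deg",
    "direction_histogram_bins_0_359",
    "n_tracks",
)


def write_report(kinematics, summary, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the per-cell and population report CSVs.

    The per-cell table has one row per (cell, frame) with position,
    displacement over the binning interval, angle of trajectory, angle of
    deflection and MSD at the lag from track start. The population table has
    one row per frame with the averages, the percentage of cells turning more
    than 90 degrees, and the 360-bin direction histogram (semicolon-joined
    counts for bins [0,1), ..., [359,360)).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        per_cell = kinematics.table.loc[:, list(PER_CELL_COLUMNS)]
        per_cell_path = out_dir / "per_cell.csv"
        per_cell.to_csv(per_cell_path, index=False)

        pop = summary.table.copy()
        pop["direction_histogram_bins_0_359"] = [
            ";".join(str(int(c)) for c in hist)
            for hist in pop["direction_histogram_bins_0_359"]
        ]
        pop_path = out_dir / "population.csv"
        pop.loc[:, list(POPULATION_COLUMNS)].to_csv(
            pop_path, index=False
        )
    except OSError as exc:
        raise OSError(f"cannot write report to {out_dir}: {exc}") from exc
    return {"per_cell": per_cell_path, "population": pop_path}


def load_config_file(path: str | os.PathLike) -> dict:
    """Load a run-configuration file (YAML/JSON mapping or key=value lines)."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
        if isinstance(data, dict):
            return data
    except yaml.YAMLError:
        pass
    config: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"cannot parse config line: {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        try:
            config[key] = yaml.safe_load(value)
        except yaml.YAMLError:
            config[key] = value
    return config
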