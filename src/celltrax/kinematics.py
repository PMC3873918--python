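"""Per-cell and population migration kinematics at an overlapping interval size.

All angular quantities follow the compass convention of the field of view:
angles are measured counterclockwise from the +x axis *with y pointing up on
screen*, so a cell moving up-and-right at equal rates has a trajectory angle
of 45 degrees. Detections and tracks store screen (y-down) coordinates; the
flip happens in exactly one place, :func:`angle_of_trajectory`.

The angle of deflection is the signed turn between two consecutive trajectory
legs sharing an endpoint: clockwise positive, counterclockwise negative, in
(-180, 180]. Zero displacement yields an *undefined* (NaN) angle, never 0°,
so stationary cells do not masquerade as eastward movers; undefined values
are excluded from every aggregate.

Metrics are computed over overlapping intervals of size ``a`` (frame ``n`` to
``n + a``, ``n`` sliding by 1), which suppresses sub-cellular positional
jitter while keeping per-frame time resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AcquisitionConfig, Track


def angle_of_trajectory(dx_px, dy_px):
    """Direction of a displacement in degrees [0, 360), or NaN if zero.

    ``dx_px``/``dy_px`` are screen-convention displacements (y down); the
    returned angle is the compass reading with y up, so (1, 0) -> 0°,
    (0, -1) i.e. up on screen -> 90°, (-1, 0) -> 180°. Accepts scalars or
    arrays.
    """
    dx = np.asarray(dx_px, dtype=float)
    dy = np.asarray(dy_px, dtype=float)
    theta = np.degrees(np.arctan2(-dy, dx)) % 360.0
    theta = np.where((dx == 0) & (dy == 0), np.nan, theta)
    return float(theta) if theta.ndim == 0 else theta


def angle_of_deflection(theta_prev, theta_curr):
    """Signed turn from one trajectory angle to the next, in (-180, 180].

    Clockwise turns (decreasing compass angle) are positive, counterclockwise
    negative; an exact reversal maps to +180 to keep the range half-open.
    NaN in either argument propagates. Accepts scalars or arrays.
    """
    tp = np.asarray(theta_prev, dtype=float)
    tc = np.asarray(theta_curr, dtype=float)
    d = tp - tc  # clockwise positive
    wrapped = -(((-d + 180.0) % 360.0) - 180.0)  # (-180, 180]
    wrapped = np.where(np.isnan(tp) | np.isnan(tc), np.nan, wrapped)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, in [0, 360); NaN-aware.

    Exposed alongside the plain arithmetic mean used in the population report
    because the arithmetic mean is discontinuous at the 360°/0° wrap.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    mean = float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)
    return 0.0 if mean >= 360.0 else mean  # guard the float artifact (-eps % 360 == 360.0)


def interval_pairs(track: Track, a: int) -> list[tuple[int, int]]:
    """All frame pairs (n, n+a) present in the track, n sliding by 1.

    Intervals overlap: a track of L contiguous frames yields L - a pairs.
    Tracks with frame gaps only contribute pairs whose both endpoints exist.
    """
    if a < 1:
        raise ValueError("interval size a must be >= 1")
    present = set(track.frames.tolist())
    return [(n, n + a) for n in sorted(present) if n + a in present]


def displacement_and_speed(
    p_n: Sequence[float], p_na: Sequence[float], config: AcquisitionConfig
) -> tuple[float, float]:
    """Euclidean displacement (px) over one interval and speed in µm/hour.

    speed = displacement_px * pixel_size_um * 60 / (frame_interval_min * a),
    with ``a`` the configured interval size.
    """
    d = float(np.hypot(p_na[0] - p_n[0], p_na[1] - p_n[1]))
    speed = d * config.pixel_size_um * 60.0 / (config.frame_interval_min * config.interval_size)
    return d, speed


def msd(track: Track, lag_frames: int) -> float:
    """Mean squared displacement (px²) at a frame lag, over all overlapping starts.

    Returns NaN when the track holds no pair separated by exactly
    ``lag_frames`` frames.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    frames = track.frames
    xy = track.xy
    index = {int(f): i for i, f in enumerate(frames)}
    sq = [
        float(((xy[index[f + lag_frames]] - xy[i]) ** 2).sum())
        for i, f in enumerate(frames)
        if f + lag_frames in index
    ]
    return float(np.mean(sq)) if sq else float("nan")


@dataclass(frozen=True)
class KinematicsTable:
    """Per-cell per-frame kinematics at a fixed interval size.

    ``table`` columns: cell_id, frame, x, y, displacement_px (over
    [frame, frame+a]), theta_trajectory_deg (of that leg), theta_deflection_deg
    (turn at this frame between legs [frame-a, frame] and [frame, frame+a]),
    msd_px2 (at lag = frame - track start). Undefined values are NaN.
    """

    table: pd.DataFrame
    interval_size: int


@dataclass(frozen=True)
class PopulationSummary:
    """Per-frame population aggregates.

    ``table`` columns: frame, avg_displacement_px, avg_theta_trajectory_deg
    (arithmetic mean of defined angles), pct_turning_gt_90,
    avg_abs_deflection_deg, direction_histogram_bins_0_359 (length-360 count
    array per row), n_tracks.
    """

    table: pd.DataFrame


def compute_kinematics(tracks: Iterable[Track], config: AcquisitionConfig) -> KinematicsTable:
    """Build the per-cell kinematics table for all tracks at interval size a."""
    a = config.interval_size
    rows = []
    for tr in tracks:
        frames = tr.frames
        xy = tr.xy
        index = {int(f): i for i, f in enumerate(frames)}
        first = int(frames[0])
        # trajectory angle of the leg starting at each frame, where defined
        theta_of_leg: dict[int, float] = {}
        for n, na in interval_pairs(tr, a):
            d = xy[index[na]] - xy[index[n]]
            theta_of_leg[n] = angle_of_trajectory(d[0], d[1])
        # msd at every lag present in this track (vectorized on contiguous frames)
        msd_at_lag = {0: 0.0}
        contiguous = bool(np.all(np.diff(frames) == 1))
        if contiguous:
            n_pts = len(frames)
            for lag in range(1, n_pts):
                d = xy[lag:] - xy[:-lag]
                msd_at_lag[lag] = float((d * d).sum(axis=1).mean())
        else:
            for f in frames[1:]:
                lag = int(f) - first
                msd_at_lag[lag] = msd(tr, lag)
        for i, f in enumerate(frames):
            f = int(f)
            disp = np.nan
            theta = np.nan
            if (f + a) in index:
                d = xy[index[f + a]] - xy[i]
                disp = float(np.hypot(d[0], d[1]))
                theta = theta_of_leg.get(f, np.nan)
            defl = angle_of_deflection(
                theta_of_leg.get(f - a, np.nan), theta_of_leg.get(f, np.nan)
            )
            rows.append(
                (
                    tr.cell_id,
                    f,
                    float(xy[i, 0]),
                    float(xy[i, 1]),
                    disp,
                    theta,
                    defl,
                    msd_at_lag.get(f - first, np.nan),
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "frame",
            "x",
            "y",
            "displacement_px",
            "theta_trajectory_deg",
            "theta_deflection_deg",
            "msd_px2",
        ],
    )
    return KinematicsTable(table=table, interval_size=a)


def summarize_population(kinematics: KinematicsTable) -> PopulationSummary:
    """Aggregate the kinematics table per frame.

    Averages run over cells with defined values only. ``pct_turning_gt_90`` is
    the percentage of defined deflections exceeding 90° in magnitude;
    ``avg_abs_deflection_deg`` is the population mean of |deflection| (lower =
    more persistent migration). The direction histogram counts defined
    trajectory angles into integer-degree bins [k, k+1), k = 0..359.
    """
    rows = []
    for frame, grp in kinematics.table.groupby("frame", sort=True):
        disp = grp["displacement_px"].dropna()
        theta = grp["theta_trajectory_deg"].dropna()
        defl = grp["theta_deflection_deg"].dropna()
        hist = np.zeros(360, dtype=int)
        if len(theta):
            binned = np.floor(theta.to_numpy()).astype(int) % 360
            np.add.at(hist, binned, 1)
        rows.append(
            (
                int(frame),
                float(disp.mean()) if len(disp) else np.nan,
                float(theta.mean()) if len(theta) else np.nan,
                float(100.0 * (defl.abs() > 90.0).mean()) if len(defl) else np.nan,
                float(defl.abs().mean()) if len(defl) else np.nan,
                hist,
                int(grp["cell_id"].nunique()),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "avg_displacement_px",
            "avg_theta_trajectory_deg",
            "pct_turning_gt_90",
            "avg_abs_deflection_deg",
            "direction_histogram_bins_0_359",
            "n_tracks",
        ],
    )
    return PopulationSummary(table=table)
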