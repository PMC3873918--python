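"""Collective-migration quantification via paired directional variance (PRMI).

The paired random migration index is the mean, over pairs of neighboring
cells, of the pairwise *sample* standard deviation of their trajectory angles:
for a pair this is |θa − θb| / √2. Perfectly collective populations score 0;
independent uniform directions score 120/√2 ≈ 84.85°, the statistic's null
ceiling. Pairs in which one cell heads 0–90° and the other 270–360° are
excluded, because the raw angle difference across the 360°/0° wrap would
inflate the apparent variance.

Two controls accompany the nearest-neighbor statistic: *random pairing*
(partners drawn uniformly among all tracked cells in the same frame,
distances ignored) separates local from global directional coupling, and
*random angles* (each cell's direction replaced by an independent uniform
draw, exclusion off) realizes the null ceiling on the same data layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AcquisitionConfig
from .kinematics import KinematicsTable

SQRT2 = float(np.sqrt(2.0))

#: Minimum pooled pair count for a reportable PRMI value.
MIN_REPORTABLE_PAIRS = 100


@dataclass(frozen=True)
class PRMIResult:
    """A PRMI value with its provenance.

    prmi_deg : mean pairwise sample SD of trajectory angles, degrees (>= 0).
    n_pairs : pairs pooled over the frame window.
    mode : 'nearest_neighbor', 'random_pairing' or 'random_angles'.
    exclusion_applied : whether wrap-straddling pairs were removed.
    neighbor_mode : 'nearest' (each cell's single nearest cell, gated) or
        'all_pairs' (every pair within the radius).
    frame_window : (first_frame, last_frame) pooled, inclusive.
    """

    prmi_deg: float
    n_pairs: int
    mode: str
    exclusion_applied: bool
    neighbor_mode: str
    frame_window: tuple[int, int]


def pair_angle_sd(theta_a, theta_b):
    """Sample standard deviation of two angles: |θa − θb| / √2.

    Computed on raw angle values, no circular wrapping — the exclusion rule
    handles pairs straddling the 360°/0° discontinuity. Accepts arrays.
    """
    d = np.abs(np.asarray(theta_a, dtype=float) - np.asarray(theta_b, dtype=float))
    out = d / SQRT2
    return float(out) if out.ndim == 0 else out


def apply_exclusion(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop pairs with one angle in [0, 90] and the other in [270, 360).

    Such pairs straddle the wrap of the angle scale and would report a falsely
    high directional spread. All other pairs are retained.
    """
    a = pairs["theta_a"].to_numpy(dtype=float)
    b = pairs["theta_b"].to_numpy(dtype=float)
    low_a, low_b = (a >= 0) & (a <= 90), (b >= 0) & (b <= 90)
    high_a, high_b = (a >= 270) & (a < 360), (b >= 270) & (b < 360)
    drop = (low_a & high_b) | (high_a & low_b)
    return pairs.loc[~drop].reset_index(drop=True)


def neighbor_pairs(
    frame_df: pd.DataFrame,
    radius_um: float,
    config: AcquisitionConfig,
    neighbor_mode: str = "nearest",
) -> pd.DataFrame:
    """Neighbor pairs with defined trajectory angles at one frame.

    ``frame_df`` needs columns cell_id, x, y (pixels) and
    theta_trajectory_deg; rows with undefined angles are ignored. In
    ``'nearest'`` mode (default) each cell is paired with its single nearest
    other cell, the pair kept when the inter-centroid distance is within
    ``radius_um``; reciprocal duplicates collapse to one unordered pair.
    ``'all_pairs'`` keeps every pair within the radius. Columns of the result:
    frame, cell_a, cell_b, distance_um, theta_a, theta_b.
    """
    if neighbor_mode not in ("nearest", "all_pairs"):
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")
    df = frame_df.dropna(subset=["theta_trajectory_deg"]).reset_index(drop=True)
    n = len(df)
    cols = ["frame", "cell_a", "cell_b", "distance_um", "theta_a", "theta_b"]
    if n < 2:
        return pd.DataFrame(columns=cols)
    xy_um = df[["x", "y"]].to_numpy(dtype=float) * config.pixel_size_um
    diff = xy_um[:, None, :] - xy_um[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    frame = int(df["frame"].iloc[0]) if "frame" in df.columns else 0
    ids = df["cell_id"].to_numpy()
    theta = df["theta_trajectory_deg"].to_numpy(dtype=float)
    seen: set[tuple] = set()
    rows = []
    if neighbor_mode == "nearest":
        nn = np.argmin(dist, axis=1)
        for i in range(n):
            j = int(nn[i])
            if dist[i, j] > radius_um:
                continue
            key = (min(ids[i], ids[j]), max(ids[i], ids[j]))
            if key in seen:
                continue
            seen.add(key)
            rows.append((frame, ids[i], ids[j], float(dist[i, j]), theta[i], theta[j]))
    else:
        ii, jj = np.nonzero(np.triu(dist <= radius_um, k=1))
        for i, j in zip(ii, jj):
            rows.append((frame, ids[i], ids[j], float(dist[i, j]), theta[i], theta[j]))
    return pd.DataFrame(rows, columns=cols)


def _frame_tables(kinematics: KinematicsTable, frame_window: tuple[int, int] | None):
    table = kinematics.table
    if frame_window is None:
        frame_window = (int(table["frame"].min()), int(table["frame"].max()))
    lo, hi = frame_window
    sub = table[(table["frame"] >= lo) & (table["frame"] <= hi)]
    return frame_window, [grp for _, grp in sub.groupby("frame", sort=True)]


def prmi(
    kinematics: KinematicsTable,
    config: AcquisitionConfig,
    mode: str = "nearest_neighbor",
    frame_window: tuple[int, int] | None = None,
    radius_um: float = 100.0,
    neighbor_mode: str = "nearest",
    seed: int | None = None,
) -> PRMIResult:
    """Compute PRMI over a frame window, pooling pairs across frames.

    Modes: ``'nearest_neighbor'`` (neighbor pairs, exclusion applied),
    ``'random_pairing'`` (per-frame uniform re-draw of partners among all
    cells with defined angles, distances ignored, exclusion applied) and
    ``'random_angles'`` (neighbor pairs but every angle replaced by an
    independent uniform draw on [0, 360), exclusion *not* applied — with
    exclusion the uniform ceiling would drop to ≈ 69.7° instead of the
    ≈ 84.85° null). The random modes require a seed and are bit-reproducible
    for equal seeds. Fewer than 100 pooled pairs triggers a warning; zero
    pairs yields NaN.
    """
    if mode not in ("nearest_neighbor", "random_pairing", "random_angles"):
        raise ValueError(f"unknown PRMI mode {mode!r}")
    if mode != "nearest_neighbor" and seed is None:
        raise ValueError(f"mode {mode!r} requires a seed")
    rng = np.random.default_rng(seed) if seed is not None else None
    frame_window, frames = _frame_tables(kinematics, frame_window)

    sds: list[np.ndarray] = []
    n_pairs = 0
    exclusion_applied = mode != "random_angles"
    for grp in frames:
        if mode == "random_pairing":
            defined = grp.dropna(subset=["theta_trajectory_deg"])
            m = len(defined)
            if m < 2:
                continue
            theta = defined["theta_trajectory_deg"].to_numpy(dtype=float)
            ids = defined["cell_id"].to_numpy()
            partner = rng.integers(0, m - 1, size=m)
            partner = np.where(partner >= np.arange(m), partner + 1, partner)
            pairs = pd.DataFrame(
                {
                    "frame": int(grp["frame"].iloc[0]),
                    "cell_a": ids,
                    "cell_b": ids[partner],
                    "distance_um": np.nan,
                    "theta_a": theta,
                    "theta_b": theta[partner],
                }
            )
            pairs = apply_exclusion(pairs)
        else:
            pairs = neighbor_pairs(grp, radius_um, config, neighbor_mode=neighbor_mode)
            if mode == "random_angles":
                if len(pairs):
                    pairs = pairs.assign(
                        theta_a=rng.uniform(0.0, 360.0, size=len(pairs)),
                        theta_b=rng.uniform(0.0, 360.0, size=len(pairs)),
                    )
            else:
                pairs = apply_exclusion(pairs)
        if len(pairs):
            sds.append(pair_angle_sd(pairs["theta_a"], pairs["theta_b"]))
            n_pairs += len(pairs)

    if n_pairs == 0:
        value = float("nan")
    else:
        value = float(np.concatenate(sds).mean())
        if n_pairs <= MIN_REPORTABLE_PAIRS:
            warnings.warn(
                f"PRMI computed from only {n_pairs} pairs (> {MIN_REPORTABLE_PAIRS} "
                "recommended for a reportable value)",
                stacklevel=2,
            )
    return PRMIResult(
        prmi_deg=value,
        n_pairs=n_pairs,
        mode=mode,
        exclusion_applied=exclusion_applied,
        neighbor_mode=neighbor_mode,
        frame_window=frame_window,
    )


def pair_table(
    kinematics: KinematicsTable,
    config: AcquisitionConfig,
    frame_window: tuple[int, int] | None = None,
    radius_um: float = 100.0,
    neighbor_mode: str = "nearest",
) -> pd.DataFrame:
    """Exclusion-filtered neighbor-pair table pooled over a frame window."""
    _, frames = _frame_tables(kinematics, frame_window)
    parts = []
    for grp in frames:
        pairs = apply_exclusion(
            neighbor_pairs(grp, radius_um, config, neighbor_mode=neighbor_mode)
        )
        if len(pairs):
            pairs = pairs.assign(sd_deg=pair_angle_sd(pairs["theta_a"], pairs["theta_b"]))
            parts.append(pairs)
    if not parts:
        return pd.DataFrame(
            columns=["frame", "cell_a", "cell_b", "distance_um", "theta_a", "theta_b", "sd_deg"]
        )
    return pd.concat(parts, ignore_index=True)


def leading_edge_profile(
    kinematics: KinematicsTable,
    config: AcquisitionConfig,
    frame_windows: list[tuple[int, int]],
    edge_axis: str = "x",
    bin_width_um: float = 100.0,
    radius_um: float = 100.0,
    neighbor_mode: str = "nearest",
    edge_position_um: float | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """PRMI as a function of distance from a sheet's leading edge.

    Cells are assigned to distance bins at the start of each frame window,
    using their coordinate along ``edge_axis`` ('x' or 'y'); the edge position
    defaults to the extreme (minimum) occupied coordinate at that frame.
    Within each (bin, window), nearest-neighbor PRMI with exclusion is pooled
    over the window's frames. Bins with fewer than ``min_pairs`` pairs report
    NaN rather than zero. Returns columns bin_start_um, window_start,
    window_end, prmi_deg, n_pairs.
    """
    if edge_axis not in ("x", "y"):
        raise ValueError("edge_axis must be 'x' or 'y'")
    table = kinematics.table
    rows = []
    for lo, hi in frame_windows:
        window = table[(table["frame"] >= lo) & (table["frame"] <= hi)]
        if window.empty:
            continue
        start_frame = int(window["frame"].min())
        at_start = window[window["frame"] == start_frame]
        coord = at_start.set_index("cell_id")[edge_axis] * config.pixel_size_um
        edge = float(coord.min()) if edge_position_um is None else edge_position_um
        bin_of_cell = ((coord - edge) // bin_width_um).astype(int)
        for b in sorted(bin_of_cell.unique()):
            members = set(bin_of_cell.index[bin_of_cell == b])
            sub = window[window["cell_id"].isin(members)]
            sds: list[np.ndarray] = []
            n_pairs = 0
            for _, grp in sub.groupby("frame", sort=True):
                pairs = apply_exclusion(
                    neighbor_pairs(grp, radius_um, config, neighbor_mode=neighbor_mode)
                )
                if len(pairs):
                    sds.append(pair_angle_sd(pairs["theta_a"], pairs["theta_b"]))
                    n_pairs += len(pairs)
            value = (
                float(np.concatenate(sds).mean()) if n_pairs >= min_pairs else float("nan")
            )
            rows.append((float(b * bin_width_um), lo, hi, value, n_pairs))
    return pd.DataFrame(
        rows, columns=["bin_start_um", "window_start", "window_end", "prmi_deg", "n_pairs"]
    )
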