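"""Frame-to-frame linking of detections into tracks.

Links are formed per frame pair by greedy ascending-cost assignment on squared
displacement, gated by a maximum displacement per frame stepped. At nuclear
densities typical of these experiments (tens of µm spacing versus a few µm of
motion per frame) this agrees with a global assignment while remaining easy to
verify. Conflicts are resolved by smaller cost, then smaller detection index,
which makes the result independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection import Detection
from .io_formats import Track


@dataclass(frozen=True)
class LinkingParams:
    """Linking parameters.

    max_disp_px_per_frame : float
        How far a cell is tolerated to migrate from frame to frame, in pixels.
    min_track_length : int
        Tracks with fewer points are discarded (>= 2).
    link_range : int
        Number of frames a link may skip when a detection is missed (default 1,
        i.e. no gap closing). Skipped frames keep their gap: positions are
        never interpolated.
    """

    max_disp_px_per_frame: float = 10.0
    min_track_length: int = 2
    link_range: int = 1

    def __post_init__(self) -> None:
        if not self.max_disp_px_per_frame > 0:
            raise ValueError("max_disp_px_per_frame must be positive")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.link_range < 1:
            raise ValueError("link_range must be >= 1")


def link(detections_by_frame: Sequence[Sequence[Detection]], params: LinkingParams) -> list[Track]:
    """Assemble per-frame detections into tracks.

    ``detections_by_frame[i]`` holds the detections of frame ``i``. Each
    detection joins at most one track; a track's consecutive points are at
    most ``max_disp * frames_stepped`` apart. Unmatched detections start new
    tracks; tracks not extended within ``link_range`` frames terminate.
    Tracks shorter than ``min_track_length`` are discarded. Cell ids are
    assigned in order of track creation (first frame, then spatial order).
    """
    # sort within each frame by (y, x) so the result is input-order invariant
    frames: list[list[Detection]] = [
        sorted(frame_dets, key=lambda d: (d.y_px, d.x_px))
        for frame_dets in detections_by_frame
    ]

    # active track state: list of dicts with last frame/position and points
    active: list[dict] = []
    finished: list[list[tuple[int, float, float]]] = []

    for f, dets in enumerate(frames):
        # candidate links: (cost, track_slot, det_index)
        candidates = []
        for ti, tr in enumerate(active):
            df = f - tr["last_frame"]
            if df < 1 or df > params.link_range:
                continue
            gate2 = (params.max_disp_px_per_frame * df) ** 2
            for di, det in enumerate(dets):
                cost = (det.x_px - tr["x"]) ** 2 + (det.y_px - tr["y"]) ** 2
                if cost <= gate2:
                    candidates.append((cost, ti, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for cost, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            det = dets[di]
            tr = active[ti]
            tr["points"].append((f, det.x_px, det.y_px))
            tr["last_frame"] = f
            tr["x"], tr["y"] = det.x_px, det.y_px
        # retire tracks that can no longer be extended
        still_active = []
        for tr in active:
            if f - tr["last_frame"] >= params.link_range:
                finished.append(tr["points"])
            else:
                still_active.append(tr)
        active = still_active
        # unmatched detections seed new tracks
        for di, det in enumerate(dets):
            if di not in used_dets:
                active.append(
                    {
                        "points": [(f, det.x_px, det.y_px)],
                        "last_frame": f,
                        "x": det.x_px,
                        "y": det.y_px,
                    }
                )
    finished.extend(tr["points"] for tr in active)

    finished.sort(key=lambda pts: (pts[0][0], pts[0][2], pts[0][1]))  # first frame, y, x
    tracks = [
        Track(cell_id=i, points=np.asarray(pts, dtype=float))
        for i, pts in enumerate(p for p in finished if len(p) >= 2)
    ]
    return filter_tracks(tracks, params.min_track_length)


def filter_tracks(tracks: Sequence[Track], min_track_length: int) -> list[Track]:
    """Keep only tracks with at least ``min_track_length`` points."""
    return [t for t in tracks if len(t) >= min_track_length]
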