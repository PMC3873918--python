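"""Persistence time from the persistent-random-walk MSD model, and turn bias.

The persistent random walk predicts a mean squared displacement

    MSD(t) = n_d * S^2 * P * (t - P * (1 - exp(-t / P)))

with ``n_d`` the dimensionality (2 here), ``S`` the cell speed and ``P`` the
persistence time — the timescale of directional memory. MSD grows
ballistically (~ n_d S² t² / 2) for t << P and diffusively (~ n_d S² P t) for
t >> P; the crossover locates P. Fitting is nonlinear least squares with
multiple starts in P, because the model's large-t plateau in parameter space
traps single-start optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_formats import AcquisitionConfig, Track
from .kinematics import msd as track_msd


@dataclass(frozen=True)
class PersistenceFit:
    """Result of a persistent-random-walk MSD fit.

    S is in µm/min, P in minutes. ``converged`` is False when the optimizer
    failed from every start or when P exceeds the fitted lag range (the model
    is then unidentifiable from the data: a ballistic track looks this way).
    """

    S: float
    P: float
    n_d: int
    rss: float
    n_lags_used: int
    converged: bool


def prw_msd_model(t, S: float, P: float, n_d: int = 2):
    """Persistent-random-walk MSD at time(s) ``t`` (same time units as P)."""
    if P <= 0:
        raise ValueError("persistence time P must be positive")
    t = np.asarray(t, dtype=float)
    out = n_d * S**2 * P * (t - P * (1.0 - np.exp(-t / P)))
    return float(out) if out.ndim == 0 else out


def population_msd(
    tracks: Iterable[Track],
    config: AcquisitionConfig,
    max_lag_min: float = 240.0,
) -> pd.DataFrame:
    """Population-averaged MSD curve in µm² versus lag time in minutes.

    Squared displacements are pooled over all tracks and all overlapping start
    frames at each lag, then averaged, which weights cells by the number of
    windows they contribute (the standard pooled estimator).
    """
    max_lag_frames = int(np.floor(max_lag_min / config.frame_interval_min))
    sums = np.zeros(max_lag_frames + 1)
    counts = np.zeros(max_lag_frames + 1, dtype=int)
    for tr in tracks:
        frames = tr.frames
        xy = tr.xy
        if np.all(np.diff(frames) == 1):
            for lag in range(1, min(max_lag_frames, len(frames) - 1) + 1):
                d = xy[lag:] - xy[:-lag]
                sums[lag] += (d * d).sum()
                counts[lag] += d.shape[0]
        else:
            index = {int(f): i for i, f in enumerate(frames)}
            for i, f in enumerate(frames):
                for lag in range(1, max_lag_frames + 1):
                    j = index.get(int(f) + lag)
                    if j is not None:
                        sums[lag] += ((xy[j] - xy[i]) ** 2).sum()
                        counts[lag] += 1
    lags = np.nonzero(counts)[0]
    lags = lags[lags > 0]
    return pd.DataFrame(
        {
            "lag_min": lags * config.frame_interval_min,
            "msd_um2": (sums[lags] / counts[lags]) * config.pixel_size_um**2,
            "n_pairs": counts[lags],
        }
    )


_P_STARTS_MIN = (7.0, 30.0, 120.0, 480.0)


def fit_persistence(
    msd_curve: pd.DataFrame | Sequence[tuple[float, float]],
    fit_window: tuple[float, float] = (0.0, 240.0),
    n_d: int = 2,
) -> PersistenceFit:
    """Fit (S, P) of the persistent-random-walk model to an MSD curve.

    ``msd_curve`` is a DataFrame with columns lag_min / msd_um2 (or an
    iterable of such pairs); only lags inside ``fit_window`` (minutes,
    half-open at the left) enter the unweighted least-squares fit, and at
    least 4 points are required. Starts cover P from one frame interval to
    8 hours, with S seeded from the ballistic limit of the first point.
    ``converged`` is False if no start succeeds or the fitted P exceeds the
    largest fitted lag (unidentifiable: the data never leave the ballistic
    regime).
    """
    if isinstance(msd_curve, pd.DataFrame):
        t = msd_curve["lag_min"].to_numpy(dtype=float)
        y = msd_curve["msd_um2"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(msd_curve), dtype=float)
        t, y = arr[:, 0], arr[:, 1]
    keep = (t > fit_window[0]) & (t <= fit_window[1]) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if t.size < 4:
        raise ValueError(f"need >= 4 MSD points inside fit window, got {t.size}")
    order = np.argsort(t)
    t, y = t[order], y[order]

    s0 = float(np.sqrt(max(2.0 * y[0] / (n_d * t[0] ** 2), 1e-12)))

    def residuals(params):
        s, p = params
        return prw_msd_model(t, s, p, n_d) - y

    best = None
    for p0 in _P_STARTS_MIN:
        try:
            sol = least_squares(
                residuals,
                x0=[s0, p0],
                bounds=([0.0, 1e-6], [np.inf, np.inf]),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
        except Exception:  # noqa: BLE001 - a failed start is simply skipped
            continue
        if not sol.success:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return PersistenceFit(
            S=float("nan"), P=float("nan"), n_d=n_d, rss=float("nan"),
            n_lags_used=int(t.size), converged=False,
        )
    rss, sol = best
    s_hat, p_hat = float(sol.x[0]), float(sol.x[1])
    identifiable = p_hat <= float(t[-1])
    return PersistenceFit(
        S=s_hat, P=p_hat, n_d=n_d, rss=rss, n_lags_used=int(t.size),
        converged=identifiable,
    )


def fit_persistence_tracks(
    tracks: Sequence[Track],
    config: AcquisitionConfig,
    fit_window: tuple[float, float] = (0.0, 240.0),
    per_cell: bool = False,
) -> PersistenceFit | pd.DataFrame:
    """Fit persistence from tracks: population-averaged MSD by default.

    With ``per_cell=True`` each track's own MSD curve is fitted and a
    DataFrame (cell_id, S, P, rss, n_lags, converged) is returned; per-cell
    fits are noisier and may fail on short tracks (flagged, not raised).
    """
    if not per_cell:
        curve = population_msd(tracks, config, max_lag_min=fit_window[1])
        return fit_persistence(curve, fit_window=fit_window)
    rows = []
    for tr in tracks:
        curve = population_msd([tr], config, max_lag_min=fit_window[1])
        try:
            fit = fit_persistence(curve, fit_window=fit_window)
        except ValueError:
            fit = PersistenceFit(float("nan"), float("nan"), 2, float("nan"), 0, False)
        rows.append((tr.cell_id, fit.S, fit.P, fit.rss, fit.n_lags_used, fit.converged))
    return pd.DataFrame(rows, columns=["cell_id", "S", "P", "rss", "n_lags", "converged"])


def right_turn_fraction(deflections) -> float:
    """Percentage of a cell's nonzero deflections that are clockwise (> 0).

    NaN (undefined) and exactly-zero deflections are excluded from the
    denominator; with sub-pixel centroids exact zeros have measure ~0.
    Returns NaN when no nonzero defined deflection exists.
    """
    d = np.asarray(deflections, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    if d.size == 0:
        return float("nan")
    return float(100.0 * (d > 0).mean())
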