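"""Per-track apparent diffusion coefficients and bound/mobile classification.

For each track the lag-1 mean-squared displacement over consecutive frames
gives the apparent diffusion coefficient

    D* = MSD / (4 dt),

which is biased upward by localization error; the corrected coefficient

    Dcorrected = MSD / (4 dt) - sigma_loc^2 / dt

removes that bias (it may be negative and is deliberately not clipped —
clipping would bias the bound fraction).  Molecules are classified BOUND
when Dcorrected falls below a threshold (default 0.1 µm²/s).

Tracks are also segmented into alternating binding/diffusing intervals from
the instantaneous D* in a sliding window, resolving the sub-second
"search" binding events that punctuate free diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import AcquisitionSettings

__all__ = [
    "MotionStats",
    "DiffusionSummary",
    "track_msd",
    "compute_motion_stats",
    "classify_tracks",
    "segment_intervals",
]


class TrackTooShortError(ValueError):
    """Track has fewer steps than required for a D* estimate."""


@dataclass
class MotionStats:
    track_id: int
    msd_lag1: float          # µm²
    D_star: float            # µm²/s
    D_corrected: float       # µm²/s (may be negative)
    n_steps: int
    classification: str = ""


@dataclass
class DiffusionSummary:
    bound_fraction: float            # percent
    n_tracks: int
    n_bound: int
    mean_D_star_bound: float
    mean_D_star_mobile: float        # "average apparent D of unbound molecules"
    threshold: float
    used_corrected: bool
    hist_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    stats: pd.DataFrame | None = None


def track_msd(track: pd.DataFrame, settings: AcquisitionSettings,
              min_steps: int = 4) -> MotionStats:
    """Lag-1 MSD and apparent diffusion coefficients for one track.

    Only displacements between consecutive frames enter the MSD:
    displacements across memory gaps span more than one frame interval and
    would bias D*, so they are excluded.  The step count requirement applies
    to the track length (localizations - 1), as in 'at least four steps'.
    """
    track = track.sort_values("frame")
    frames = track["frame"].to_numpy()
    if len(frames) - 1 < min_steps:
        raise TrackTooShortError(
            f"track has {len(frames) - 1} steps; {min_steps} required"
        )
    x = track["x_um"].to_numpy()
    y = track["y_um"].to_numpy()
    consec = np.diff(frames) == 1
    d2 = np.diff(x) ** 2 + np.diff(y) ** 2
    msd = float(d2[consec].mean()) if consec.any() else np.nan
    dt = settings.dt
    d_star = msd / (4.0 * dt)
    d_corr = d_star - settings.sigma_loc**2 / dt
    tid = int(track["track_id"].iloc[0]) if "track_id" in track else -1
    return MotionStats(tid, msd, d_star, d_corr, int(len(frames) - 1))


def compute_motion_stats(tracks: pd.DataFrame, settings: AcquisitionSettings,
                         min_steps: int = 4) -> pd.DataFrame:
    """Per-track motion statistics for every sufficiently long track."""
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        try:
            st = track_msd(grp, settings, min_steps=min_steps)
        except TrackTooShortError:
            continue
        rows.append((tid, st.msd_lag1, st.D_star, st.D_corrected, st.n_steps))
    return pd.DataFrame(
        rows, columns=["track_id", "msd_lag1", "D_star", "D_corrected", "n_steps"]
    )


def classify_tracks(
    stats: pd.DataFrame,
    threshold: float = 0.1,
    use_corrected: bool = True,
    hist_bins: int = 40,
    hist_range: tuple[float, float] = (-2.5, 1.5),
) -> DiffusionSummary:
    """Bound/mobile split of a motion-statistics table.

    A track is BOUND iff its (corrected, by default) apparent diffusion
    coefficient is below ``threshold``.  Also returns the log10 D*
    histogram used for population displays.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(stats) == 0:
        raise ValueError("no tracks to classify")
    d = stats["D_corrected"] if use_corrected else stats["D_star"]
    bound = (d < threshold).to_numpy()
    d_star = stats["D_star"].to_numpy()
    pos = d_star[d_star > 0]
    edges = np.linspace(*hist_range, hist_bins + 1)
    counts, _ = np.histogram(np.log10(pos) if pos.size else pos, bins=edges)
    out = stats.copy()
    out["classification"] = np.where(bound, "BOUND", "MOBILE")
    return DiffusionSummary(
        bound_fraction=100.0 * bound.sum() / len(stats),
        n_tracks=int(len(stats)),
        n_bound=int(bound.sum()),
        mean_D_star_bound=float(d_star[bound].mean()) if bound.any() else np.nan,
        mean_D_star_mobile=float(d_star[~bound].mean()) if (~bound).any() else np.nan,
        threshold=threshold,
        used_corrected=use_corrected,
        hist_edges=edges,
        hist_counts=counts,
        stats=out,
    )


def segment_intervals(
    track: pd.DataFrame,
    settings: AcquisitionSettings,
    window: int = 5,
    threshold: float = 0.1,
    min_duration: int = 3,
) -> list[tuple[str, float, float]]:
    """Segment one track into BOUND / MOBILE intervals.

    The instantaneous apparent diffusion coefficient is computed over a
    sliding window of ``window`` steps; contiguous runs below/above
    ``threshold`` lasting at least ``min_duration`` frames become
    intervals, and shorter runs are merged into their flanking state.

    Returns a list of (state, start_s, duration_s).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    track = track.sort_values("frame")
    frames = track["frame"].to_numpy()
    n = len(frames)
    if n <= window:
        raise ValueError("track shorter than the sliding window")
    x = track["x_um"].to_numpy()
    y = track["y_um"].to_numpy()
    d2 = np.diff(x) ** 2 + np.diff(y) ** 2
    consec = np.diff(frames) == 1
    # centered sliding-window instantaneous D*, per localization
    inst = np.empty(n)
    half = window // 2
    dt = settings.dt
    for i in range(n):
        lo = max(0, i - half)
        hi = min(len(d2), lo + window)
        lo = max(0, hi - window)
        sel = consec[lo:hi]
        if sel.any():
            msd = d2[lo:hi][sel].mean()
            inst[i] = msd / (4 * dt) - settings.sigma_loc**2 / dt
        else:
            inst[i] = np.nan
    labels = np.where(inst < threshold, 0, 1)  # 0 = BOUND, 1 = MOBILE

    runs = _runs(labels)
    runs = _merge_short_runs(runs, min_duration)
    out = []
    for lab, start, length in runs:
        t0 = frames[start] * dt
        out.append(("BOUND" if lab == 0 else "MOBILE", float(t0), float(length * dt)))
    return out


def _runs(labels: np.ndarray) -> list[list]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([int(labels[start]), start, i - start])
            start = i
    return runs


def _merge_short_runs(runs: list[list], min_duration: int) -> list[list]:
    """Iteratively flip the shortest sub-threshold run into its flank."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [r[2] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_duration:
            break
        runs[i][0] = 1 - runs[i][0]
        # merge with identical neighbours
        merged = [runs[0]]
        for r in runs[1:]:
            if r[0] == merged[-1][0]:
                merged[-1][2] += r[2]
            else:
                merged.append(r)
        runs = merged
    return runs
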