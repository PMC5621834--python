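"""Link localizations across frames into single-molecule tracks.

Localizations appearing in consecutive frames within a search radius are
linked; a memory parameter lets a track survive short blinking or defocus
gaps.  Ambiguities are resolved per frame by a globally optimal one-to-one
assignment: minimize

    sum of squared displacements + radius^2 * (number of unmatched items),

which always prefers making a feasible link (d <= radius) over leaving both
ends unmatched, is deterministic, and is order-independent.  Displacements
across a gap of g skipped frames are allowed up to radius * sqrt(g + 1)
(Brownian scaling of the search distance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["link_tracks"]

_BIG = 1e12


def _assign(prev_xy: np.ndarray, cur_xy: np.ndarray,
            max_r: np.ndarray) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between previous track heads and current
    localizations.  ``max_r[i]`` is the per-track allowed radius.

    Returns (track_index, localization_index) pairs.
    """
    n_t, n_l = len(prev_xy), len(cur_xy)
    if n_t == 0 or n_l == 0:
        return []
    d2 = ((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(axis=2)
    feasible = d2 <= (max_r[:, None] ** 2)
    cost = np.where(feasible, d2, _BIG)
    # augmented square matrix: dummy "unmatched" nodes at cost radius^2
    size = n_t + n_l
    M = np.full((size, size), _BIG)
    M[:n_t, :n_l] = cost
    M[:n_t, n_l:] = _BIG
    M[n_t:, :n_l] = _BIG
    np.fill_diagonal(M[:n_t, n_l:], max_r**2)
    base_r2 = float(np.max(max_r) ** 2)
    np.fill_diagonal(M[n_t:, :n_l], base_r2)
    M[n_t:, n_l:] = 0.0
    rows, cols = linear_sum_assignment(M)
    out = []
    for r, c in zip(rows, cols):
        if r < n_t and c < n_l and feasible[r, c]:
            out.append((int(r), int(c)))
    return out


def link_tracks(
    locs: pd.DataFrame,
    radius: float,
    memory: int = 1,
    min_steps: int = 4,
) -> pd.DataFrame:
    """Link a localization table into tracks.

    Parameters
    ----------
    locs
        Table with columns ``frame``, ``x_um``, ``y_um`` (extra columns are
        carried through).
    radius
        Maximum frame-to-frame linking distance, µm (0.48 for the fast
        acquisition regime, 0.192 for the slow one).
    memory
        Number of consecutive frames a molecule may go undetected
        (blink / defocus) without terminating its track.
    min_steps
        Minimum number of steps (localizations - 1) for a track to be kept.

    Returns
    -------
    DataFrame of the input rows that were linked, with added ``track_id``
    and ``gap`` (1 if the link from the previous localization skipped
    frames) columns, sorted by (track_id, frame).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if memory < 0 or min_steps < 1:
        raise ValueError("memory must be >= 0 and min_steps >= 1")
    if locs.empty:
        return locs.assign(track_id=pd.Series(dtype=int), gap=pd.Series(dtype=int))
    dup = locs.duplicated(subset=["frame", "x_um", "y_um"])
    if dup.any():
        raise ValueError("duplicate (frame, position) rows in localization table")

    locs = locs.sort_values(["frame", "x_um", "y_um"], kind="mergesort").reset_index(drop=True)
    frames = np.sort(locs["frame"].unique())

    next_id = 0
    # active track state: id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    assignment = np.full(len(locs), -1, dtype=int)
    gap_flag = np.zeros(len(locs), dtype=np.int8)

    grouped = {f: idx.to_numpy() for f, idx in locs.groupby("frame").groups.items()}
    for f in frames:
        idx = grouped[f]
        cur_xy = locs.loc[idx, ["x_um", "y_um"]].to_numpy()
        ids = sorted(active.keys())
        cand_ids, prev_xy, max_r, gaps = [], [], [], []
        for tid in ids:
            lf, x, y = active[tid]
            skip = f - lf - 1
            if skip <= memory:
                cand_ids.append(tid)
                prev_xy.append((x, y))
                max_r.append(radius * np.sqrt(skip + 1))
                gaps.append(skip)
        matches = _assign(np.asarray(prev_xy, dtype=float).reshape(-1, 2),
                          cur_xy, np.asarray(max_r, dtype=float))
        matched_locs = set()
        for ti, li in matches:
            tid = cand_ids[ti]
            row = idx[li]
            assignment[row] = tid
            gap_flag[row] = 1 if gaps[ti] > 0 else 0
            active[tid] = (int(f), cur_xy[li, 0], cur_xy[li, 1])
            matched_locs.add(li)
        # expire tracks whose gap now exceeds the memory
        for tid in list(active.keys()):
            if f - active[tid][0] - 1 > memory:
                del active[tid]
        for li in range(len(idx)):
            if li not in matched_locs:
                row = idx[li]
                assignment[row] = next_id
                active[next_id] = (int(f), cur_xy[li, 0], cur_xy[li, 1])
                next_id += 1

    out = locs.assign(track_id=assignment, gap=gap_flag)
    sizes = out.groupby("track_id")["frame"].size()
    keep = sizes[sizes >= min_steps + 1].index
    out = out[out["track_id"].isin(keep)]
    out = out.sort_values(["track_id", "frame"]).reset_index(drop=True)
    # renumber track ids densely for stable output
    remap = {tid: i for i, tid in enumerate(out["track_id"].unique())}
    out["track_id"] = out["track_id"].map(remap)
    return out
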