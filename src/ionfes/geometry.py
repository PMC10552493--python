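"""Descriptive geometric analyses of ion-chelator trajectories.

Pure functions producing flat tables: per-group chelate-angle scatter data
with normalized histograms, ligand/solvent-split partial coordination
curves, and level-crossing segmentation of coordination-number time series
(dual-threshold hysteresis on a running-mean-smoothed signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cvs import CVSeries, chelate_angles, partial_coordination_curve


def angle_scatter_table(traj: np.ndarray, triplet_spec: dict,
                        n_hist_bins: int = 36):
    """Ion-O-X angle pairs per frame and group, plus unit-area histograms.

    ``triplet_spec`` maps group name -> ((ion, O, X1), (ion, O, X2)): the
    two angles measured at the same oxygen vertex toward two different
    partner atoms (N-side and C-side in a real hydroxamate).  Groups with
    out-of-range indices are skipped with a warning column rather than
    aborting the analysis.
    """
    traj = np.asarray(traj, dtype=float)
    n_atoms = traj.shape[1]
    rows = []
    skipped = []
    for name, (trip_a, trip_b) in triplet_spec.items():
        if max(max(trip_a), max(trip_b)) >= n_atoms:
            skipped.append(name)
            continue
        for t, frame in enumerate(traj):
            a, b = chelate_angles(frame, [trip_a, trip_b])
            rows.append((t, name, a, b))
    table = pd.DataFrame(rows, columns=["frame", "group", "angle_ON", "angle_OC"])
    edges = np.linspace(0.0, 180.0, n_hist_bins + 1)
    hists = {}
    for name, grp in table.groupby("group"):
        hists[name] = {
            "edges": edges,
            "angle_ON": np.histogram(grp["angle_ON"], bins=edges, density=True)[0],
            "angle_OC": np.histogram(grp["angle_OC"], bins=edges, density=True)[0],
        }
    return table, hists, skipped


def coordination_split_curve(traj: np.ndarray, center: int, ligand_members,
                             solvent_members, r_grid: np.ndarray) -> pd.DataFrame:
    """Sharp n(r) curves for ligand and solvent oxygens separately.

    The two member sets must be disjoint; by construction the curves sum to
    the combined all-oxygen curve.
    """
    lig = set(int(i) for i in ligand_members)
    sol = set(int(i) for i in solvent_members)
    if lig & sol:
        raise ValueError("ligand and solvent member sets overlap")
    r_grid = np.asarray(r_grid, dtype=float)
    n_lig = partial_coordination_curve(traj, center, sorted(lig), r_grid)
    n_sol = (partial_coordination_curve(traj, center, sorted(sol), r_grid)
             if sol else np.zeros_like(r_grid))
    return pd.DataFrame({"r": r_grid, "n_ligand": n_lig, "n_solvent": n_sol,
                         "n_total": n_lig + n_sol})


@dataclass
class TransitionSummary:
    segments: pd.DataFrame   # columns: start, stop, level (frame indices, inclusive/exclusive)
    crossings: pd.DataFrame  # columns: frame, time, from_level, to_level
    smoothed: np.ndarray


def cn_transition_summary(series: CVSeries, levels, band: float = 0.25,
                          smooth_window: int = 50) -> TransitionSummary:
    """Segment a CV time series into dwells around given levels.

    The series is smoothed by a running mean of ``smooth_window`` frames;
    the state switches to a level only when the smoothed signal enters that
    level's +-band (dual-threshold hysteresis), and the crossing is stamped
    at the first such frame.  Requires >= 2 sorted levels and a series at
    least one smoothing window long.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2 or np.any(np.diff(levels) <= 0):
        raise ValueError("need >= 2 strictly ascending levels")
    x = series.primary
    if x.size < smooth_window:
        raise ValueError("series shorter than the smoothing window")
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.convolve(x, kernel, mode="valid")
    offset = smooth_window - 1  # smoothed sample i covers frames [i, i+offset]
    state = None
    state_start = 0
    seg_rows = []
    cross_rows = []
    for i, v in enumerate(sm):
        inside = np.flatnonzero(np.abs(v - levels) <= band)
        if inside.size == 0:
            continue
        lvl = float(levels[inside[np.argmin(np.abs(v - levels[inside]))]])
        if state is None:
            state = lvl
            state_start = i
        elif lvl != state:
            frame = i + offset
            seg_rows.append((state_start, i, state))
            cross_rows.append((frame, float(series.time[frame]), state, lvl))
            state = lvl
            state_start = i
    if state is not None:
        seg_rows.append((state_start, sm.size, state))
    segments = pd.DataFrame(seg_rows, columns=["start", "stop", "level"])
    crossings = pd.DataFrame(cross_rows,
                             columns=["frame", "time", "from_level", "to_level"])
    return TransitionSummary(segments=segments, crossings=crossings, smoothed=sm)
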