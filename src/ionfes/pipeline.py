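"""End-to-end study orchestration: build -> umbrella set -> WHAM -> 2D
reweight -> bootstrap -> quench scan -> geometric analyses -> report.

A study is driven by one YAML config (see :func:`default_config` for the
documented schema).  Stage outputs are plain-text files in the output
directory; completed umbrella windows are detected by their COLVAR files
and skipped on re-run, so interrupted studies resume where they stopped.
Estimator stages are deterministic given the config, so re-running a
finished study reproduces its tables bitwise.
"""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cvs import cv_values
from .geometry import angle_scatter_table, cn_transition_summary, coordination_split_curve
from .io import (load_config, load_series_from_manifest, read_xyz, save_config,
                 write_colvar, write_manifest, write_xyz)
from .minimize import inherent_structure_scan
from .simulate import (SimConfig, UmbrellaWindow, histogram_overlap,
                       run_trajectory, umbrella_centers)
from .synthetic import build_toy_chelator
from .wham import bootstrap_errors, reweight_2d, wham_1d

log = logging.getLogger("ionfes.pipeline")


def default_config(analog: str = "dfo", output_dir: str = "study_out") -> dict:
    """Study configuration mirroring the printed umbrella protocol in
    reduced units: bias k = 20 kBT, centers 2..6 (trihydroxamate analog,
    9 windows) or 2..8 (tetrahydroxamate analog, 13 windows) in steps of
    0.5, switching cutoffs r0 = 5 (ligand) / 2.5 (solvent), dt = 0.002,
    gamma = 2, nonbonded cutoff 11."""
    if analog not in ("dfo", "4hms"):
        raise ValueError("analog must be 'dfo' or '4hms'")
    n_groups = 3 if analog == "dfo" else 4
    stop = 6.0 if analog == "dfo" else 8.0
    return {
        "system": {"n_groups": n_groups, "ring_radius": 3.0, "tether_k": 0.5,
                   "n_solvent": 12, "solvent_radius": 4.0,
                   "r0_ligand": 5.0, "r0_solvent": 2.5},
        "windows": {"start": 2.0, "stop": stop, "step": 0.5, "k": 20.0},
        "simulation": {"dt": 0.002, "gamma": 2.0, "temperature": 1.0,
                       "n_steps": 20000, "save_stride": 10,
                       "equil_fraction": 0.1},
        "estimator": {"n_bins": 100, "tol": 1.0e-8, "max_iter": 100000,
                      "n_boot": 20, "block_fraction": 0.05, "y_bins": 40},
        "quench": {"n_frames": 20, "strip_solvent": True, "force_tol": 1.0e-4},
        "analysis": {"r_grid_max": 8.0, "r_grid_points": 81,
                     "transition_levels": "auto", "smooth_window": 20},
        "seed": 2023,
        "output_dir": output_dir,
    }


def build_system(cfg: dict):
    sys_cfg = cfg["system"]
    return build_toy_chelator(
        n_groups=sys_cfg["n_groups"], ring_radius=sys_cfg["ring_radius"],
        tether_k=sys_cfg["tether_k"], seed=cfg["seed"],
        n_solvent=sys_cfg.get("n_solvent", 0),
        solvent_radius=sys_cfg.get("solvent_radius", 4.0),
        r0_ligand=sys_cfg.get("r0_ligand", 5.0),
        r0_solvent=sys_cfg.get("r0_solvent", 2.5))


def study_windows(cfg: dict, cv) -> list[UmbrellaWindow]:
    w = cfg["windows"]
    centers = umbrella_centers(w["start"], w["stop"], w["step"])
    return [UmbrellaWindow(cv, float(c), float(w["k"])) for c in centers]


def plan(cfg: dict) -> list[str]:
    w = cfg["windows"]
    n_win = len(umbrella_centers(w["start"], w["stop"], w["step"]))
    return [
        f"build: {cfg['system']['n_groups']}-group chelator analog, "
        f"{cfg['system'].get('n_solvent', 0)} solvent beads",
        f"simulate: {n_win} umbrella windows (centers {w['start']}..{w['stop']} "
        f"step {w['step']}, k={w['k']}), {cfg['simulation']['n_steps']} steps each",
        "wham: 1D free-energy profile with bootstrap errors",
        "reweight2d: (ligand CN, solvent CN) surface",
        f"quench: inherent-structure scan of {cfg.get('quench', {}).get('n_frames', 20)} frames",
        "analyze: chelate angles, coordination split curves, CN transitions",
        "report: run_record.json",
    ]


def run_study(config, dry_run: bool = False) -> dict:
    """Run (or resume) the full toy study; returns a dict of output paths."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    if dry_run:
        for line in plan(cfg):
            log.info("plan: %s", line)
        return {"plan": plan(cfg)}
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    system, cv_lig, cv_sol = build_system(cfg)
    windows = study_windows(cfg, cv_lig)
    sim = cfg["simulation"]

    # --- umbrella windows (resumable, ladder initial conditions) ----------
    colvar_paths, xyz_paths = [], []
    start_positions = system.positions
    for i, w in enumerate(windows):
        cpath = out / f"window_{i:02d}.colvar"
        xpath = out / f"window_{i:02d}.xyz"
        colvar_paths.append(cpath)
        xyz_paths.append(xpath)
        if cpath.exists() and xpath.exists():
            log.info("window %d: found %s, skipping", i, cpath.name)
            frames, _ = read_xyz(xpath)
            start_positions = frames[-1]
            continue
        t_w = _time.time()
        res = run_trajectory(
            system.with_positions(start_positions),
            SimConfig(dt=sim["dt"], gamma=sim.get("gamma", 2.0),
                      temperature=sim.get("temperature", 1.0),
                      n_steps=sim["n_steps"],
                      save_stride=sim.get("save_stride", 10),
                      seed=cfg["seed"] + i),
            window=w, secondary_cv=cv_sol)
        start_positions = res.final_positions
        n_skip = int(sim.get("equil_fraction", 0.1) * len(res.series))
        write_colvar(cpath, res.series.sliced(n_skip))
        write_xyz(xpath, res.frames[n_skip:], system.roles,
                  comment=f"window {i} center={w.center} k={w.k}")
        log.info("window %d (center=%.2f, seed=%d): %d frames kept, %.1fs",
                 i, w.center, cfg["seed"] + i, len(res.series) - n_skip,
                 _time.time() - t_w)
    manifest = out / "manifest.csv"
    write_manifest(manifest, windows, [p.name for p in colvar_paths])

    # --- WHAM 1D + bootstrap ----------------------------------------------
    est = cfg["estimator"]
    series = load_series_from_manifest(manifest)
    for i in range(len(series) - 1):
        ov = histogram_overlap(series[i], series[i + 1])
        log.info("window overlap %d-%d: %.3f", i, i + 1, ov)
    profile = wham_1d(series, n_bins=est["n_bins"], tol=est["tol"],
                      max_iter=est["max_iter"])
    surface_kwargs = {"y_bins": est.get("y_bins", 40)} if cv_sol else None
    err1, err2 = bootstrap_errors(series, n_boot=est["n_boot"], seed=cfg["seed"],
                                  block_fraction=est.get("block_fraction", 0.05),
                                  bin_edges=profile.bin_edges, tol=est["tol"],
                                  max_iter=est["max_iter"],
                                  surface_kwargs=surface_kwargs)
    profile.f_errors = err1
    fes1 = pd.DataFrame({"cv": profile.bin_centers, "f_kbt": profile.f_values,
                         "f_err_kbt": err1, "counts": profile.counts,
                         "unsampled": ~profile.sampled})
    fes1.to_csv(out / "fes_1d.csv", index=False)

    # --- 2D reweighting ----------------------------------------------------
    paths = {"manifest": manifest, "fes_1d": out / "fes_1d.csv"}
    if cv_sol is not None:
        surface = reweight_2d(series, profile, y_bins=est.get("y_bins", 40))
        surface.f_errors = err2
        xg, yg = np.meshgrid(surface.x_centers, surface.y_centers, indexing="ij")
        fes2 = pd.DataFrame({
            "cv_ligand": xg.ravel(), "cv_water": yg.ravel(),
            "f_kbt": surface.f_values.ravel(),
            "f_err_kbt": (err2.ravel() if err2 is not None else np.nan),
            "n_eff": surface.n_eff.ravel(),
            "unsampled": ~surface.sampled.ravel()})
        fes2.to_csv(out / "fes_2d.csv", index=False)
        paths["fes_2d"] = out / "fes_2d.csv"

    # --- inherent-structure quench scan ------------------------------------
    q = cfg.get("quench", {"n_frames": 20, "strip_solvent": True,
                           "force_tol": 1e-4})
    all_frames = [read_xyz(p)[0] for p in xyz_paths]
    pool = np.concatenate(all_frames)
    rng = np.random.default_rng(cfg["seed"] + 10_000)
    pick = rng.choice(len(pool), size=min(q["n_frames"], len(pool)), replace=False)
    quench_table = inherent_structure_scan(
        pool[np.sort(pick)], system, cv_lig,
        strip_solvent_first=q.get("strip_solvent", True),
        force_tol=q.get("force_tol", 1e-4))
    quench_table.to_csv(out / "quench.csv", index=False)
    paths["quench"] = out / "quench.csv"

    # --- geometric analyses -------------------------------------------------
    ana = cfg.get("analysis", {})
    mid = len(all_frames) // 2
    traj = all_frames[mid]
    triplets = {}
    lig = system.indices_of("ligand_oxygen")
    back = system.indices_of("backbone")
    for g in range(cfg["system"]["n_groups"]):
        o1, o2 = int(lig[2 * g]), int(lig[2 * g + 1])
        b = int(back[g])
        # toy analogs of the ion-O-N / ion-O-C angle pairs: partner atoms are
        # the backbone bead and the sibling oxygen of the same group
        triplets[f"group{g + 1}"] = ((0, o1, b), (0, o1, o2))
    table, hists, skipped = angle_scatter_table(traj, triplets)
    table.to_csv(out / "angles.csv", index=False)
    r_grid = np.linspace(0.0, ana.get("r_grid_max", 8.0),
                         ana.get("r_grid_points", 81))
    split = coordination_split_curve(traj, 0, lig,
                                     system.indices_of("solvent_oxygen"), r_grid)
    split.to_csv(out / "coordination.csv", index=False)
    cn_series = series[len(series) // 2]
    levels = ana.get("transition_levels", "auto")
    if levels == "auto":
        lo, hi = np.quantile(cn_series.primary, [0.1, 0.9])
        levels = [float(lo), float(hi)] if hi - lo > 0.1 else None
    if levels is not None:
        summary = cn_transition_summary(cn_series, levels,
                                        smooth_window=min(ana.get("smooth_window", 20),
                                                          max(2, len(cn_series) // 4)))
        summary.crossings.to_csv(out / "transitions.csv", index=False)
        paths["transitions"] = out / "transitions.csv"
    paths["angles"] = out / "angles.csv"
    paths["coordination"] = out / "coordination.csv"

    # --- machine-readable run record ---------------------------------------
    record = {
        "version": __version__,
        "config": cfg,
        "window_seeds": [cfg["seed"] + i for i in range(len(windows))],
        "n_windows": len(windows),
        "wham": {"converged": bool(profile.converged),
                 "n_iterations": int(profile.n_iterations),
                 "residual": float(profile.residual),
                 "n_components": int(profile.n_components)},
        "skipped_angle_groups": skipped,
        "wall_time_s": round(_time.time() - t0, 2),
    }
    with open(out / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=2)
    paths["run_record"] = out / "run_record.json"
    log.info("study complete in %.1fs -> %s", record["wall_time_s"], out)
    return {k: str(v) for k, v in paths.items()}


def write_default_config(path, analog: str = "dfo",
                         output_dir: str = "study_out") -> dict:
    cfg = default_config(analog, output_dir)
    save_config(cfg, path)
    return cfg
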