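"""Langevin (NVT) dynamics of toy systems with optional umbrella biases.

The integrator is the B-A-O-A-B splitting: half-kick, half-drift, exact
Ornstein-Uhlenbeck friction/noise step, half-drift, half-kick.  With
``gamma = 0`` and ``temperature = 0`` it reduces to velocity Verlet.  The
defaults mirror the production molecular-dynamics settings mapped into
reduced units: dt = 0.002, gamma = 2, kBT = 1, nonbonded cutoff 11.

An umbrella window puts a harmonic bias ``k/2 (CN - s0)^2`` on a
coordination-number CV; window ladders start each window from the final
frame of the previous one and are seeded as ``base_seed + window_index``,
so every trajectory is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvs import CVSeries, CVSpec, coordination_number
from .potentials import EnergyModel, ToySystem, bias_energy_force

#: potential energies beyond this magnitude abort the run as divergence
_ENERGY_GUARD = 1e12


class SimulationError(RuntimeError):
    """Raised when a trajectory diverges; the message names the step."""


@dataclass(frozen=True)
class SimConfig:
    """Integrator settings (reduced units)."""

    dt: float = 0.002
    gamma: float = 2.0
    temperature: float = 1.0
    n_steps: int = 1000
    save_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gamma < 0 or self.temperature < 0:
            raise ValueError("require dt > 0, gamma >= 0, temperature >= 0")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonic bias k/2 (cv - center)^2 on a coordination-number CV."""

    cv: CVSpec | None
    center: float
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")


@dataclass
class TrajectoryResult:
    frames: np.ndarray            # (T, N, 3) saved configurations
    series: CVSeries              # CVs at the saved frames
    potential: np.ndarray         # unbiased potential energy per saved frame
    kinetic: np.ndarray           # kinetic energy per saved frame
    final_positions: np.ndarray
    seed: int


def run_trajectory(system: ToySystem, cfg: SimConfig,
                   window: UmbrellaWindow | None = None,
                   primary_cv: CVSpec | None = None,
                   secondary_cv: CVSpec | None = None) -> TrajectoryResult:
    """Integrate one Langevin trajectory, recording CVs every save_stride.

    The recorded primary CV is the window's CV when biased, else
    ``primary_cv``.  Deterministic for a given seed.
    """
    cv = window.cv if window is not None and window.cv is not None else primary_cv
    if cv is None:
        raise ValueError("a primary CV is required (window.cv or primary_cv)")
    model = EnergyModel(system)
    rng = np.random.default_rng(cfg.seed)
    x = np.array(system.positions, dtype=float)
    free = model.free
    m = system.masses[:, None]
    inv_m = np.where(free[:, None], 1.0 / m, 0.0)
    # exact OU step coefficients; frozen particles get no noise
    c1 = np.exp(-cfg.gamma * cfg.dt)
    sigma = np.sqrt(cfg.temperature * (1.0 - c1 * c1)) * np.sqrt(inv_m)
    v = np.sqrt(cfg.temperature * inv_m) * rng.standard_normal(x.shape)

    def forces(pos):
        u, f = model.energy_forces(pos)
        s, g = coordination_number(pos, cv)
        if window is not None and window.k > 0:
            ub, fb = bias_energy_force(s, g, window.center, window.k)
            u_tot = u + ub
            f = f + fb
            f[system.frozen] = 0.0
        else:
            u_tot = u
        return u, u_tot, f, s

    u, u_tot, f, s = forces(x)
    half = 0.5 * cfg.dt
    n_saved = cfg.n_steps // cfg.save_stride
    frames = np.empty((n_saved, *x.shape))
    prim = np.empty(n_saved)
    sec = np.empty(n_saved) if secondary_cv is not None else None
    pot = np.empty(n_saved)
    kin = np.empty(n_saved)
    times = np.empty(n_saved)
    k_saved = 0
    for step in range(1, cfg.n_steps + 1):
        v += half * f * inv_m
        x += half * v
        if cfg.gamma > 0:
            v = c1 * v + sigma * rng.standard_normal(x.shape)
        x += half * v
        u, u_tot, f, s = forces(x)
        v += half * f * inv_m
        if not np.isfinite(u_tot) or abs(u_tot) > _ENERGY_GUARD:
            raise SimulationError(
                f"energy divergence at step {step} (U={u_tot!r}); "
                "reduce dt or soften the bias")
        if step % cfg.save_stride == 0:
            frames[k_saved] = x
            prim[k_saved] = s
            if sec is not None:
                sec[k_saved] = coordination_number(x, secondary_cv)[0]
            pot[k_saved] = u
            kin[k_saved] = 0.5 * float(np.sum(m * v * v * free[:, None]))
            times[k_saved] = step * cfg.dt
            k_saved += 1
    series = CVSeries(times, prim, sec,
                      None if window is None else window.center,
                      None if window is None else window.k,
                      label=cv.label,
                      secondary_label=secondary_cv.label if secondary_cv else "cv_water")
    return TrajectoryResult(frames, series, pot, kin, x, cfg.seed)


def run_umbrella_set(system: ToySystem, windows: list[UmbrellaWindow],
                     cfg: SimConfig, secondary_cv: CVSpec | None = None,
                     equil_fraction: float = 0.1,
                     ladder: bool = True) -> list[TrajectoryResult]:
    """Run one biased trajectory per window.

    Window ``i`` is seeded ``cfg.seed + i`` and (with ``ladder=True``)
    starts from the final frame of window ``i - 1``.  The first
    ``equil_fraction`` of each saved series/trajectory is discarded as
    equilibration.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    if not 0 <= equil_fraction < 1:
        raise ValueError("equil_fraction must be in [0, 1)")
    results = []
    start = system.positions
    for i, w in enumerate(windows):
        wcfg = SimConfig(cfg.dt, cfg.gamma, cfg.temperature, cfg.n_steps,
                         cfg.save_stride, cfg.seed + i)
        try:
            res = run_trajectory(system.with_positions(start), wcfg, window=w,
                                 secondary_cv=secondary_cv)
        except SimulationError as err:
            raise SimulationError(f"window {i} (center={w.center}): {err}") from err
        if ladder:
            start = res.final_positions
        n_skip = int(equil_fraction * len(res.series))
        res = TrajectoryResult(res.frames[n_skip:], res.series.sliced(n_skip),
                               res.potential[n_skip:], res.kinetic[n_skip:],
                               res.final_positions, res.seed)
        results.append(res)
    return results


def histogram_overlap(a: CVSeries, b: CVSeries, n_bins: int = 50) -> float:
    """Overlap coefficient of two window histograms (0 = disjoint, 1 = equal).

    Adjacent umbrella windows must overlap for WHAM to connect them; this is
    the diagnostic the pipeline logs per window pair.
    """
    lo = min(a.primary.min(), b.primary.min())
    hi = max(a.primary.max(), b.primary.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a.primary, bins=edges, density=False)
    pb, _ = np.histogram(b.primary, bins=edges, density=False)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def umbrella_centers(start: float, stop: float, step: float = 0.5) -> np.ndarray:
    """Inclusive ladder of bias centers, e.g. 2..6 step 0.5 -> 9 centers."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)
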