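"""Ground-truth generators for validating the estimation stack.

Two kinds of oracle inputs are produced here:

* exact i.i.d. samples from biased densities ``exp(-[F0(s) + k/2 (s-s0)^2])``
  for a chosen ground-truth free energy ``F0`` (inverse-CDF sampling on a
  dense grid; conditional grid sampling for 2D), so the WHAM estimators can
  be checked against a known answer without any dynamics in the loop; and

* low-dimensional toy ion-chelator systems whose exact free energy along a
  coordination-number CV is computable by dense-grid quadrature
  (``reference_fes_quadrature``), the brute-force oracle for the
  end-to-end umbrella-sampling pipeline.

The default 1D ground truth is the double well ``8 (s^2 - 1)^2`` (barrier
8 kBT between wells at s = +-1), mimicking the open-vs-closed two-basin
phenomenology of chelation free-energy profiles without claiming any real
system's energetics; the 2D default adds a separable harmonic "solvent"
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvs import CVSeries, CVSpec, SwitchingParams, _switch_and_deriv
from .potentials import (BondParams, PairParams, ToySystem, lj_124_from_well,
                         pair_key)
from .simulate import UmbrellaWindow
from .wham import FreeEnergyProfile


@dataclass(frozen=True)
class DoubleWell1D:
    """F0(s) = barrier * (((s - center)/scale)^2 - 1)^2 on a finite domain."""

    barrier: float = 8.0
    center: float = 0.0
    scale: float = 1.0
    domain: tuple[float, float] = (-2.0, 2.0)

    def __call__(self, s):
        z = (np.asarray(s, dtype=float) - self.center) / self.scale
        return self.barrier * (z * z - 1.0) ** 2

    def to_dict(self) -> dict:
        return {"family": "double_well_1d", "barrier": self.barrier,
                "center": self.center, "scale": self.scale,
                "domain": list(self.domain)}


@dataclass(frozen=True)
class SeparableHarmonic2D:
    """F0(s, w) = fx(s) + c_w (w - w0)^2: a double well in the primary CV
    plus an uncoupled harmonic "solvent coordination" term."""

    fx: DoubleWell1D = DoubleWell1D()
    c_w: float = 2.0
    w0: float = 4.0
    domain_w: tuple[float, float] = (2.0, 6.0)

    def __call__(self, s, w):
        return self.fx(s) + self.c_w * (np.asarray(w, dtype=float) - self.w0) ** 2

    def to_dict(self) -> dict:
        return {"family": "separable_harmonic_2d", "fx": self.fx.to_dict(),
                "c_w": self.c_w, "w0": self.w0, "domain_w": list(self.domain_w)}


def fes_from_dict(d: dict):
    if d["family"] == "double_well_1d":
        return DoubleWell1D(d["barrier"], d["center"], d["scale"], tuple(d["domain"]))
    if d["family"] == "separable_harmonic_2d":
        return SeparableHarmonic2D(fes_from_dict(d["fx"]), d["c_w"], d["w0"],
                                   tuple(d["domain_w"]))
    raise ValueError(f"unknown ground-truth family {d['family']!r}")


def biased_cdf_1d(fes, window: UmbrellaWindow, grid_points: int = 4001):
    """Dense grid and CDF of the biased density exp(-[F0 + bias]) (for KS
    tests and inverse-CDF sampling)."""
    lo, hi = fes.domain
    s = np.linspace(lo, hi, grid_points)
    logw = -(fes(s) + 0.5 * window.k * (s - window.center) ** 2)
    w = np.exp(logw - logw.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(s))])
    if not np.isfinite(cdf[-1]) or cdf[-1] <= 0:
        raise ValueError("biased density is not integrable on the domain")
    return s, cdf / cdf[-1]


def sample_biased(fes, window: UmbrellaWindow, n: int, seed: int,
                  grid_points: int = 4001) -> CVSeries:
    """Exact i.i.d. samples from the biased density of a ground-truth FES.

    1D ground truths yield a primary-only series; 2D ground truths sample
    the primary marginal by inverse CDF and the secondary conditionally on
    a grid.  Deterministic given the seed; n = 0 returns an empty series
    with valid window metadata.
    """
    rng = np.random.default_rng(seed)
    time = np.arange(n, dtype=float)
    if isinstance(fes, SeparableHarmonic2D) or hasattr(fes, "domain_w"):
        lo, hi = fes.fx.domain
        wlo, whi = fes.domain_w
        s_grid = np.linspace(lo, hi, grid_points)
        w_grid = np.linspace(wlo, whi, 801)
        logw2 = -(fes(s_grid[:, None], w_grid[None, :])
                  + 0.5 * window.k * (s_grid[:, None] - window.center) ** 2)
        w2 = np.exp(logw2 - logw2.max())
        marg = w2.sum(axis=1)
        if marg.sum() <= 0 or not np.isfinite(marg.sum()):
            raise ValueError("biased density is not integrable on the domain")
        s_samples = _inverse_cdf_sample(s_grid, marg, rng.random(n))
        # conditional secondary draw from the grid row nearest each sample
        rows = np.clip(np.searchsorted(s_grid, s_samples), 0, grid_points - 1)
        w_samples = np.empty(n)
        u = rng.random(n)
        for row in np.unique(rows):
            sel = rows == row
            w_samples[sel] = _inverse_cdf_sample(w_grid, w2[row], u[sel])
        return CVSeries(time, s_samples, w_samples, window.center, window.k)
    s_grid, cdf = biased_cdf_1d(fes, window, grid_points)
    samples = np.interp(rng.random(n), cdf, s_grid)
    return CVSeries(time, samples, None, window.center, window.k)


def _inverse_cdf_sample(grid: np.ndarray, density: np.ndarray,
                        u: np.ndarray) -> np.ndarray:
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1])
                                           * np.diff(grid))])
    if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
        raise ValueError("density is not integrable on the grid")
    return np.interp(u, cdf / cdf[-1], grid)


# ---------------------------------------------------------------------------
# toy ion-chelator systems


def build_toy_chelator(n_groups: int = 3, ring_radius: float = 3.0,
                       tether_k: float = 0.5, seed: int = 0,
                       n_solvent: int = 0, solvent_radius: float = 4.0,
                       r0_ligand: float = 5.0, r0_solvent: float = 2.5,
                       ) -> tuple[ToySystem, CVSpec, CVSpec | None]:
    """Reduced stand-in for a hydroxamate chelator wrapped around an ion.

    One free ion sits at the origin; ``n_groups`` bidentate binding groups
    (two ligand oxygens bonded to one backbone bead each, backbone beads
    chained like the open-chain chelator) surround it, softly tethered so
    the complex neither collapses nor drifts apart.  ``n_groups = 3`` gives
    the 6-oxygen trihydroxamate analog, ``n_groups = 4`` the 8-oxygen
    tetrahydroxamate analog.  Optional solvent-oxygen beads in a tethered
    shell compete for the ion's coordination sphere.

    Returns the system, the ligand-CN CVSpec (r0 = 5 by default) and a
    solvent-CN CVSpec (r0 = 2.5) or None when there is no solvent.
    """
    if not 2 <= n_groups <= 4:
        raise ValueError("n_groups must be in 2..4")
    if ring_radius <= 0 or tether_k <= 0:
        raise ValueError("ring_radius and tether_k must be positive")
    rng = np.random.default_rng(seed)
    positions = [np.zeros(3)]
    roles = ["ion"]
    charges = [4.0]
    bonds: list[tuple[int, int, BondParams]] = []
    bond_bo = BondParams(k_bond=50.0, r_eq=1.0)
    bond_oo = BondParams(k_bond=20.0, r_eq=1.3)
    chain_eq = 0.9 * 2.0 * ring_radius * np.sin(np.pi / n_groups)
    bond_bb = BondParams(k_bond=10.0, r_eq=chain_eq)
    backbone_idx = []
    for g in range(n_groups):
        phi = 2.0 * np.pi * g / n_groups
        b_pos = ring_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        b_idx = len(positions)
        backbone_idx.append(b_idx)
        positions.append(b_pos)
        roles.append("backbone")
        charges.append(0.0)
        for sgn in (-1.0, 1.0):
            o_pos = (ring_radius - 0.9) * np.array([
                np.cos(phi + sgn * 0.22), np.sin(phi + sgn * 0.22), 0.0])
            o_idx = len(positions)
            positions.append(o_pos)
            roles.append("ligand_oxygen")
            charges.append(-0.5)
            bonds.append((b_idx, o_idx, bond_bo))
        bonds.append((o_idx - 1, o_idx, bond_oo))
    for a, b in zip(backbone_idx[:-1], backbone_idx[1:]):
        bonds.append((a, b, bond_bb))
    for s in range(n_solvent):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        positions.append(solvent_radius * u)
        roles.append("solvent_oxygen")
        charges.append(-0.2)
    positions = np.array(positions) + 0.05 * rng.standard_normal((len(positions), 3))
    n = len(positions)
    pair_table = {
        pair_key("ion", "ligand_oxygen"): lj_124_from_well(2.1, 4.0, c4=8.0,
                                                           q_product=-2.0),
        pair_key("ion", "solvent_oxygen"): lj_124_from_well(2.1, 3.0, c4=4.0,
                                                            q_product=-0.8),
        pair_key("ion", "backbone"): PairParams(c12=200.0),
        pair_key("ligand_oxygen", "ligand_oxygen"): PairParams(c12=50.0),
        pair_key("ligand_oxygen", "solvent_oxygen"): PairParams(c12=50.0),
        pair_key("solvent_oxygen", "solvent_oxygen"): PairParams(c12=50.0),
        pair_key("backbone", "backbone"): PairParams(c12=200.0),
        pair_key("backbone", "solvent_oxygen"): PairParams(c12=100.0),
    }
    tether_k_arr = np.zeros(n)
    tether_centers = np.array(positions)
    for idx, role in enumerate(roles):
        if role == "backbone":
            tether_k_arr[idx] = tether_k
        elif role == "solvent_oxygen":
            tether_k_arr[idx] = 0.5 * tether_k
    system = ToySystem(positions=positions, roles=roles,
                       charges=np.array(charges), masses=np.ones(n),
                       bonds=bonds, pair_table=pair_table,
                       tether_k=tether_k_arr, tether_centers=tether_centers)
    lig = tuple(int(i) for i in system.indices_of("ligand_oxygen"))
    cv_ligand = CVSpec(0, lig, SwitchingParams(r0=r0_ligand), label="cv_ligand")
    cv_solvent = None
    if n_solvent:
        sol = tuple(int(i) for i in system.indices_of("solvent_oxygen"))
        cv_solvent = CVSpec(0, sol, SwitchingParams(r0=r0_solvent), label="cv_water")
    return system, cv_ligand, cv_solvent


def build_single_ligand_system(r_star: float = 2.0, depth: float = 4.0,
                               tether_k: float = 0.5, r0: float = 2.5,
                               cutoff: float = 11.0) -> tuple[ToySystem, CVSpec]:
    """One mobile ligand oxygen around a frozen ion: a 3-DOF system whose
    free energy along its coordination number is quadrature-computable."""
    pair_table = {pair_key("ion", "ligand_oxygen"):
                  lj_124_from_well(r_star, depth, cutoff=cutoff)}
    system = ToySystem(positions=np.array([[0.0, 0.0, 0.0], [r_star, 0.0, 0.0]]),
                       roles=["ion", "ligand_oxygen"],
                       charges=np.array([4.0, -0.5]), masses=np.ones(2),
                       pair_table=pair_table,
                       tether_k=np.array([0.0, tether_k]),
                       frozen=np.array([True, False]))
    cv = CVSpec(0, (1,), SwitchingParams(r0=r0), label="cv_ligand")
    return system, cv


def reference_fes_quadrature(system: ToySystem, cv: CVSpec,
                             bin_edges: np.ndarray, bounds: float | None = None,
                             n_grid: int = 161, refine_check: bool = False,
                             ) -> FreeEnergyProfile | tuple[FreeEnergyProfile, float]:
    """Exact free-energy profile by dense 3D grid quadrature (oracle only).

    Requires exactly one free particle (<= 3 unconstrained coordinates):
    F(s_b) = -ln sum_{grid cells with CN in bin b} exp(-U(x)) dV, min-zero.
    With ``refine_check=True`` the quadrature is repeated at doubled
    resolution and the max per-bin change is returned alongside.
    """
    free = np.flatnonzero(~system.frozen)
    if free.size != 1:
        raise ValueError("quadrature oracle requires exactly one free particle "
                         f"(got {free.size}); freeze the rest")
    mobile = int(free[0])
    if bounds is None:
        k_t = system.tether_k[mobile]
        bounds = 6.0 if k_t <= 0 else max(4.0, 5.0 / np.sqrt(k_t))

    def profile_at(n_pts: int) -> np.ndarray:
        # evaluate plane by plane to bound memory at O(n_pts^2)
        ax = np.linspace(-bounds, bounds, n_pts)
        gy, gz = np.meshgrid(ax, ax, indexing="ij")
        plane = np.stack([np.zeros_like(gy).ravel(), gy.ravel(), gz.ravel()],
                         axis=1)
        hist = np.zeros(len(bin_edges) - 1)
        with np.errstate(over="ignore", under="ignore"):
            for x0 in ax:
                pts = plane.copy()
                pts[:, 0] = x0
                u = _single_particle_energy(system, mobile, pts)
                s = _single_particle_cn(system, cv, mobile, pts)
                h, _ = np.histogram(s, bins=bin_edges, weights=np.exp(-u))
                hist += h
        with np.errstate(divide="ignore"):
            f = -np.log(hist / hist.sum())
        f[hist == 0] = np.nan
        return f - np.nanmin(f)

    f = profile_at(n_grid)
    edges = np.asarray(bin_edges, dtype=float)
    prof = FreeEnergyProfile(bin_edges=edges, f_values=f,
                             window_offsets=np.zeros(1), converged=True,
                             n_iterations=0, residual=0.0, n_components=1,
                             counts=np.where(np.isfinite(f), 1.0, 0.0))
    if not refine_check:
        return prof
    f2 = profile_at(2 * (n_grid - 1) + 1)
    both = np.isfinite(f) & np.isfinite(f2)
    delta = float(np.max(np.abs(f[both] - f2[both]))) if both.any() else np.nan
    return prof, delta


def _single_particle_energy(system: ToySystem, mobile: int,
                            pts: np.ndarray) -> np.ndarray:
    """Potential energy terms involving the mobile particle, vectorized over
    candidate positions (constant fixed-fixed terms are omitted: they only
    shift the profile, which is min-zeroed anyway)."""
    u = np.zeros(pts.shape[0])
    role_m = system.roles[mobile]
    bonded = {frozenset((i, j)) for i, j, _ in system.bonds}
    for j in range(system.n_particles):
        if j == mobile:
            continue
        params = system.pair_table.get(pair_key(role_m, system.roles[j]))
        if params is None or frozenset((mobile, j)) in bonded:
            pass
        else:
            r = np.linalg.norm(pts - system.positions[j], axis=1)
            r = np.maximum(r, 1e-6)
            inv2 = 1.0 / (r * r)
            inv4 = inv2 * inv2
            inv6 = inv4 * inv2
            up = (params.c12 * inv6 * inv6 - params.c6 * inv6
                  - params.c4 * inv4 + params.q_product / r)
            u += np.where(r >= params.cutoff, 0.0, up)
    for i, j, bp in system.bonds:
        if mobile not in (i, j):
            continue
        other = j if i == mobile else i
        r = np.linalg.norm(pts - system.positions[other], axis=1)
        u += 0.5 * bp.k_bond * (r - bp.r_eq) ** 2
    if system.tether_k[mobile] > 0:
        dx = pts - system.tether_centers[mobile]
        u += 0.5 * system.tether_k[mobile] * np.einsum("ij,ij->i", dx, dx)
    return u


def _single_particle_cn(system: ToySystem, cv: CVSpec, mobile: int,
                        pts: np.ndarray) -> np.ndarray:
    s = np.zeros(pts.shape[0])
    if cv.center_particle == mobile:
        for j in cv.member_particles:
            r = np.linalg.norm(pts - system.positions[j], axis=1)
            s += _switch_and_deriv(r, cv.switching)[0]
        return s
    const = 0.0
    for j in cv.member_particles:
        if j == mobile:
            r = np.linalg.norm(pts - system.positions[cv.center_particle], axis=1)
            s += _switch_and_deriv(r, cv.switching)[0]
        else:
            d = np.linalg.norm(system.positions[j]
                               - system.positions[cv.center_particle])
            const += float(_switch_and_deriv(np.array(d), cv.switching)[0])
    return s + const
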