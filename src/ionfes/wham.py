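"""Weighted histogram analysis method (WHAM) for umbrella-sampled CVs.

Binned WHAM combines the biased histograms ``n_i(b)`` of windows ``i``
(harmonic biases ``U_i(s) = k_i/2 (s - s0_i)^2``, energies in kBT) through
the self-consistency equations

    p_b  proportional to  M_b / sum_i N_i exp(f_i - U_i(s_b)),
    f_i = -ln sum_b p_b exp(-U_i(s_b)),

iterated until the window offsets ``f_i`` stop changing.  The free-energy
profile is ``F(s_b) = -ln p_b`` reported with its minimum at zero over
sampled bins; bins with no counts are reported as unsampled (NaN + mask),
never interpolated.

Per-frame unbiasing weights ``w_j = 1 / sum_i N_i exp(f_i - U_i(s_j))``
reuse the converged offsets to histogram a second, unbiased CV recorded
along the same trajectories into a 2D free-energy surface.

Errors come from a Monte Carlo block bootstrap: contiguous blocks of each
window's series are resampled with replacement, the whole estimate is
re-run, and the per-bin standard deviation over replicates is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cvs import CVSeries

DEFAULT_BINS = 100
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100_000
DEFAULT_PAD = 0.25
DEFAULT_BLOCK_FRACTION = 0.05  # 1/20 of each series per bootstrap block


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile in kBT, min-zero over sampled bins."""

    bin_edges: np.ndarray
    f_values: np.ndarray          # NaN on unsampled bins
    window_offsets: np.ndarray    # the WHAM f_i per window
    converged: bool
    n_iterations: int
    residual: float
    n_components: int             # connected components of the window-overlap graph
    counts: np.ndarray            # total counts per bin
    f_errors: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def sampled(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class FreeEnergySurface2D:
    """2D free-energy surface over (primary CV, secondary CV), min-zero."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    f_values: np.ndarray          # (nx, ny), NaN on unsampled bins
    n_eff: np.ndarray             # Kish effective counts per bin
    f_errors: np.ndarray | None = None

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def sampled(self) -> np.ndarray:
        return np.isfinite(self.f_values)

    def marginal_x(self) -> np.ndarray:
        """-ln sum_y exp(-F(x, y)) over sampled bins, min-zero (NaN where
        no y-bin is sampled); must agree with the 1D profile."""
        w = np.where(self.sampled, np.exp(-np.nan_to_num(self.f_values, nan=np.inf)), 0.0)
        tot = w.sum(axis=1)
        with np.errstate(divide="ignore"):
            m = -np.log(tot)
        m[tot == 0] = np.nan
        return m - np.nanmin(m)


def _window_params(series: list[CVSeries]) -> tuple[np.ndarray, np.ndarray]:
    centers, ks = [], []
    for i, s in enumerate(series):
        if s.center is None or s.k is None:
            raise ValueError(f"series {i} carries no umbrella window metadata")
        centers.append(s.center)
        ks.append(s.k)
    return np.array(centers), np.array(ks)


def default_bin_edges(series: list[CVSeries], n_bins: int = DEFAULT_BINS,
                      pad: float = DEFAULT_PAD) -> np.ndarray:
    lo = min(float(s.primary.min()) for s in series) - pad
    hi = max(float(s.primary.max()) for s in series) + pad
    return np.linspace(lo, hi, n_bins + 1)


def _overlap_components(hist: np.ndarray) -> int:
    """Connected components of the graph joining windows that share a bin."""
    n_win = hist.shape[0]
    sampled = hist > 0
    adj = [[j for j in range(n_win) if j != i and np.any(sampled[i] & sampled[j])]
           for i in range(n_win)]
    seen = [False] * n_win
    comps = 0
    for i in range(n_win):
        if seen[i]:
            continue
        comps += 1
        stack = [i]
        while stack:
            u = stack.pop()
            if seen[u]:
                continue
            seen[u] = True
            stack.extend(adj[u])
    return comps


def wham_1d(series: list[CVSeries], bin_edges: np.ndarray | None = None,
            n_bins: int = DEFAULT_BINS, tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER,
            f_init: np.ndarray | None = None) -> FreeEnergyProfile:
    """Reconstruct the 1D free-energy profile from biased window series.

    Deterministic given its inputs; duplicating every window or permuting
    the window order leaves the profile unchanged.  Non-overlapping window
    sets still converge but are flagged through ``n_components > 1``.
    """
    if not series:
        raise ValueError("at least one window series is required")
    centers, ks = _window_params(series)
    if bin_edges is None:
        bin_edges = default_bin_edges(series, n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    hist = np.stack([np.histogram(s.primary, bins=bin_edges)[0] for s in series])
    n_i = hist.sum(axis=1).astype(float)
    if np.any(n_i == 0):
        raise ValueError("every window needs at least one count inside the bins")
    m_b = hist.sum(axis=0).astype(float)
    # biased Boltzmann factors at bin centers, (n_windows, n_bins)
    c_ib = np.exp(-0.5 * ks[:, None] * (mids[None, :] - centers[:, None]) ** 2)
    f = np.zeros(len(series)) if f_init is None else np.array(f_init, dtype=float)
    residual = np.inf
    it = 0
    expf = np.exp(f)
    for it in range(1, max_iter + 1):
        denom = (n_i * expf) @ c_ib
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, m_b / denom, 0.0)
        p_sum = p.sum()
        p /= p_sum
        z = c_ib @ p
        f_new = -np.log(z)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        expf = np.exp(f)
        if residual <= tol:
            break
    converged = residual <= tol
    with np.errstate(divide="ignore"):
        fes = -np.log(p)
    fes[m_b == 0] = np.nan
    fes -= np.nanmin(fes)
    return FreeEnergyProfile(bin_edges=bin_edges, f_values=fes, window_offsets=f,
                             converged=converged, n_iterations=it, residual=residual,
                             n_components=_overlap_components(hist), counts=m_b)


def frame_weights(series: list[CVSeries], profile: FreeEnergyProfile) -> list[np.ndarray]:
    """Per-frame unbiasing weights from the converged window offsets.

    For frame value s: w = 1 / sum_i N_i exp(f_i - U_i(s)), with the bias
    evaluated at the exact frame value (not the bin center).
    """
    centers, ks = _window_params(series)
    n_i = np.array([len(s) for s in series], dtype=float)
    f = profile.window_offsets
    out = []
    for s in series:
        u_is = 0.5 * ks[:, None] * (s.primary[None, :] - centers[:, None]) ** 2
        denom = (n_i[:, None] * np.exp(f[:, None] - u_is)).sum(axis=0)
        out.append(1.0 / denom)
    return out


def reweight_2d(series: list[CVSeries], profile: FreeEnergyProfile,
                y_bins: int = 50, y_edges: np.ndarray | None = None,
                x_edges: np.ndarray | None = None,
                pad: float = DEFAULT_PAD) -> FreeEnergySurface2D:
    """Reweight 1D-biased frames onto a (primary, secondary) 2D grid.

    Requires a converged 1D profile and a secondary CV recorded on every
    frame.  The primary axis defaults to the profile's own bins so the
    marginalization consistency check is exact in its binning.
    """
    if not profile.converged:
        raise ValueError("1D profile must be converged before 2D reweighting")
    for i, s in enumerate(series):
        if s.secondary is None:
            raise ValueError(
                f"window {i} (center={s.center}) has no secondary CV column")
    if x_edges is None:
        x_edges = profile.bin_edges
    if y_edges is None:
        lo = min(float(s.secondary.min()) for s in series) - pad
        hi = max(float(s.secondary.max()) for s in series) + pad
        y_edges = np.linspace(lo, hi, y_bins + 1)
    weights = frame_weights(series, profile)
    x = np.concatenate([s.primary for s in series])
    y = np.concatenate([s.secondary for s in series])
    w = np.concatenate(weights)
    wsum, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=w)
    w2sum, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=w * w)
    with np.errstate(divide="ignore", invalid="ignore"):
        fes = -np.log(wsum / wsum.sum())
        n_eff = np.where(w2sum > 0, wsum**2 / w2sum, 0.0)
    fes[wsum == 0] = np.nan
    fes -= np.nanmin(fes)
    return FreeEnergySurface2D(x_edges=x_edges, y_edges=np.asarray(y_edges),
                               f_values=fes, n_eff=n_eff)


def _block_resample(s: CVSeries, rng: np.random.Generator,
                    block_fraction: float) -> CVSeries:
    n = len(s)
    block = max(1, int(round(block_fraction * n)))
    if block > n:
        raise ValueError("bootstrap block length exceeds the series length")
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
    return CVSeries(s.time[:n], s.primary[idx],
                    None if s.secondary is None else s.secondary[idx],
                    s.center, s.k, s.label, s.secondary_label)


def bootstrap_errors(series: list[CVSeries], n_boot: int = 50, seed: int = 0,
                     block_fraction: float = DEFAULT_BLOCK_FRACTION,
                     resample: bool = True,
                     bin_edges: np.ndarray | None = None,
                     n_bins: int = DEFAULT_BINS, tol: float = DEFAULT_TOL,
                     max_iter: int = DEFAULT_MAX_ITER,
                     surface_kwargs: dict | None = None,
                     align: str = "minzero",
                     align_mask: np.ndarray | None = None,
                     align_mask_2d: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray | None]:
    """Monte Carlo bootstrap errors of the 1D profile (and optionally the
    2D surface when ``surface_kwargs`` is given).

    Each replicate block-resamples every window series, re-runs WHAM (warm
    started from the full-data offsets) and min-zeroes the result; errors
    are per-bin standard deviations over replicates.  Deterministic given
    the seed.  ``resample=False`` re-estimates on identical data (errors
    are then exactly zero) and exists to make the resampling step testable.

    A free-energy profile is defined only up to an additive constant, and
    the min-zero convention ties that constant to whichever bin happens to
    sit lowest -- harmless for plotting, but it pins the error to zero at
    the anchor bin and lets the anchor hop between degenerate minima.
    ``align="lsq"`` instead aligns every replicate to the full-data profile
    by its mean offset over ``align_mask`` bins (default: all common bins)
    before taking the spread, giving shape errors in a well-defined gauge;
    pass the same mask that any downstream comparison uses, since high-F
    bins are orders of magnitude noisier and would dominate the offset.
    """
    if align not in ("minzero", "lsq"):
        raise ValueError("align must be 'minzero' or 'lsq'")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    base = wham_1d(series, bin_edges=bin_edges, n_bins=n_bins, tol=tol,
                   max_iter=max_iter)
    if bin_edges is None:
        bin_edges = base.bin_edges
    reps = []
    reps2d = [] if surface_kwargs is not None else None
    for _ in range(n_boot):
        rep_series = ([_block_resample(s, rng, block_fraction) for s in series]
                      if resample else list(series))
        prof = wham_1d(rep_series, bin_edges=bin_edges, tol=tol,
                       max_iter=max_iter, f_init=base.window_offsets)
        rep = prof.f_values
        if align == "lsq":
            rep = rep - _mean_offset(rep, base.f_values, align_mask)
        reps.append(rep)
        if reps2d is not None:
            surf = reweight_2d(rep_series, prof, **surface_kwargs)
            rep2 = surf.f_values
            if align == "lsq":
                base2 = _base_surface(series, base, surface_kwargs)
                rep2 = rep2 - _mean_offset(rep2, base2, align_mask_2d)
            reps2d.append(rep2)
    err1 = _nanstd(np.stack(reps))
    err2 = _nanstd(np.stack(reps2d)) if reps2d is not None else None
    return err1, err2


def _mean_offset(rep: np.ndarray, base: np.ndarray,
                 mask: np.ndarray | None) -> float:
    d = rep - base
    if mask is not None:
        d = np.where(mask, d, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        off = np.nanmean(d)
    return 0.0 if not np.isfinite(off) else float(off)


def _base_surface(series, base_profile, surface_kwargs,
                  _cache: dict = {}) -> np.ndarray:
    key = id(base_profile)
    if key not in _cache:
        _cache.clear()
        _cache[key] = reweight_2d(series, base_profile, **surface_kwargs).f_values
    return _cache[key]


def _nanstd(stack: np.ndarray) -> np.ndarray:
    """Std over replicates, ignoring replicates where a bin went unsampled."""
    count = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        out = np.nanstd(stack, axis=0, ddof=1)
    return np.where(count >= 2, out, np.nan)
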