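"""Independent maximum-likelihood WHAM used only for cross-validation.

The binned WHAM solution is the unique minimum (up to a gauge constant) of
the convex function

    A(g) = sum_b M_b ln( sum_i N_i exp(g_i - U_i(s_b)) ) - sum_i N_i g_i,

over window offsets ``g``.  This module solves that optimization directly
with scipy's L-BFGS-B and rebuilds the profile from the optimal offsets.
It shares no code with the self-consistent iteration in :mod:`ionfes.wham`
and exists so the two routes can be compared on fixtures; it is not the
production estimator.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .cvs import CVSeries


def ml_wham_1d(series: list[CVSeries], bin_edges: np.ndarray) -> np.ndarray:
    """Min-zero free-energy profile (NaN on unsampled bins) by direct
    minimization of the WHAM negative log-likelihood."""
    centers = np.array([s.center for s in series], dtype=float)
    ks = np.array([s.k for s in series], dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    hist = np.stack([np.histogram(s.primary, bins=bin_edges)[0] for s in series])
    n_i = hist.sum(axis=1).astype(float)
    m_b = hist.sum(axis=0).astype(float)
    u_ib = 0.5 * ks[:, None] * (mids[None, :] - centers[:, None]) ** 2

    def objective(g):
        a_ib = g[:, None] - u_ib + np.log(n_i)[:, None]
        a_max = a_ib.max(axis=0)
        lse = a_max + np.log(np.exp(a_ib - a_max).sum(axis=0))
        val = float(np.sum(m_b * lse) - np.sum(n_i * g))
        resp = np.exp(a_ib - lse)                   # (n_win, n_bins), sums to 1 per bin
        grad = resp @ m_b - n_i
        return val, grad

    res = _scipy_minimize(objective, np.zeros(len(series)), jac=True,
                          method="L-BFGS-B",
                          options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    g = res.x
    a_ib = g[:, None] - u_ib + np.log(n_i)[:, None]
    a_max = a_ib.max(axis=0)
    denom = np.exp(a_max) * np.exp(a_ib - a_max).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, m_b / denom, 0.0)
        fes = -np.log(p / p.sum())
    fes[m_b == 0] = np.nan
    return fes - np.nanmin(fes)
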