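"""WHAM self-consistency, 2D reweighting and bootstrap errors."""

import numpy as np
import pytest

from ionfes.cvs import CVSeries
from ionfes.simulate import UmbrellaWindow
from ionfes.synthetic import DoubleWell1D, SeparableHarmonic2D, sample_biased
from ionfes.wham import (bootstrap_errors, reweight_2d, wham_1d)


def _gaussian_series(center, k, n, seed, secondary=None):
    rng = np.random.default_rng(seed)
    s = center + rng.standard_normal(n) / np.sqrt(k)
    sec = None if secondary is None else np.full(n, secondary)
    return CVSeries(np.arange(n, dtype=float), s, sec, center, k)


def _double_well_series(n_windows=7, n=8000, seed=100, k=20.0):
    fes = DoubleWell1D()
    return [sample_biased(fes, UmbrellaWindow(None, float(c), k), n, seed + i)
            for i, c in enumerate(np.linspace(-1.8, 1.8, n_windows))]


class TestWham1D:
    def test_unbiased_single_window_is_log_histogram(self, rng):
        samples = rng.standard_normal(20000)
        series = CVSeries(np.arange(20000.0), samples, None, 0.0, 0.0)
        profile = wham_1d([series], n_bins=40)
        hist, _ = np.histogram(samples, bins=profile.bin_edges)
        with np.errstate(divide="ignore"):
            expected = -np.log(hist / hist.sum())
        expected -= expected[hist > 0].min()
        ok = hist > 0
        assert np.allclose(profile.f_values[ok], expected[ok], atol=1e-10)
        assert np.all(np.isnan(profile.f_values[~ok]))

    def test_duplicating_windows_leaves_profile_unchanged(self):
        series = _double_well_series()
        p1 = wham_1d(series)
        p2 = wham_1d(series + series, bin_edges=p1.bin_edges)
        ok = p1.sampled
        assert np.allclose(p1.f_values[ok], p2.f_values[ok], atol=1e-8)

    def test_window_order_invariance(self):
        series = _double_well_series()
        p1 = wham_1d(series)
        p2 = wham_1d(series[::-1], bin_edges=p1.bin_edges)
        ok = p1.sampled
        assert np.allclose(p1.f_values[ok], p2.f_values[ok], atol=1e-10)

    def test_min_zero_convention(self):
        p = wham_1d(_double_well_series())
        assert np.nanmin(p.f_values) == 0.0

    def test_offset_gauge_invariance(self):
        # adding a constant to all window offsets must not change the profile
        series = _double_well_series()
        p1 = wham_1d(series)
        p2 = wham_1d(series, bin_edges=p1.bin_edges,
                     f_init=p1.window_offsets + 7.0)
        assert np.allclose(p1.f_values[p1.sampled], p2.f_values[p2.sampled],
                           atol=1e-6)

    def test_disconnected_windows_flagged(self):
        far_apart = [_gaussian_series(0.0, 400.0, 4000, 1),
                     _gaussian_series(50.0, 400.0, 4000, 2)]
        profile = wham_1d(far_apart, n_bins=200)
        assert profile.n_components == 2

    def test_convergence_metadata(self):
        p = wham_1d(_double_well_series(), tol=1e-10)
        assert p.converged
        assert p.residual <= 1e-10
        assert p.n_iterations >= 1

    def test_recovers_known_gaussian_free_energy(self):
        # flat F0 + harmonic bias: unbiased F along s is flat; with two
        # overlapping windows WHAM must reproduce a flat profile
        series = [_gaussian_series(0.0, 2.0, 100000, 3),
                  _gaussian_series(0.3, 2.0, 100000, 4)]
        p = wham_1d(series, n_bins=30)
        core = p.sampled & (np.abs(p.bin_centers) < 1.0)
        spread = np.nanmax(p.f_values[core]) - np.nanmin(p.f_values[core])
        assert spread < 0.1


class TestReweight2D:
    def test_constant_secondary_degenerate_axis(self):
        series = [_gaussian_series(c, 20.0, 5000, 10 + i, secondary=4.0)
                  for i, c in enumerate((-0.3, 0.0, 0.3))]
        profile = wham_1d(series, n_bins=40)
        surface = reweight_2d(series, profile, y_bins=9)
        occupied = np.isfinite(surface.f_values).any(axis=0)
        assert occupied.sum() == 1
        j = int(np.flatnonzero(occupied)[0])
        col = surface.f_values[:, j]
        # compare where bins hold enough frames for the binned profile and
        # the per-frame reweighting to agree (tail bins differ by the
        # bin-center bias approximation)
        ok = np.isfinite(col) & (profile.counts >= 100)
        assert np.allclose(col[ok] - np.nanmin(col[ok]),
                           profile.f_values[ok] - np.nanmin(profile.f_values[ok]),
                           atol=0.05)

    def test_window_permutation_invariance(self):
        fes = SeparableHarmonic2D()
        series = [sample_biased(fes, UmbrellaWindow(None, c, 20.0), 4000, 60 + i)
                  for i, c in enumerate(np.linspace(-1.5, 1.5, 5))]
        profile = wham_1d(series)
        s1 = reweight_2d(series, profile, y_bins=20)
        profile_r = wham_1d(series[::-1], bin_edges=profile.bin_edges)
        s2 = reweight_2d(series[::-1], profile_r, y_bins=20,
                         y_edges=s1.y_edges, x_edges=s1.x_edges)
        both = s1.sampled & s2.sampled
        assert np.allclose(s1.f_values[both], s2.f_values[both], atol=1e-10)

    def test_missing_secondary_names_window(self):
        series = [_gaussian_series(0.0, 20.0, 100, 1, secondary=1.0),
                  _gaussian_series(0.5, 20.0, 100, 2)]
        profile = wham_1d(series, n_bins=20)
        with pytest.raises(ValueError, match="center=0.5"):
            reweight_2d(series, profile)

    def test_marginal_consistency_on_synthetic_2d(self):
        fes = SeparableHarmonic2D()
        series = [sample_biased(fes, UmbrellaWindow(None, c, 20.0), 20000, 80 + i)
                  for i, c in enumerate(np.linspace(-2.0, 2.0, 9))]
        profile = wham_1d(series)
        surface = reweight_2d(series, profile, y_bins=30)
        marg = surface.marginal_x()
        ok = (surface.n_eff.sum(axis=1) >= 100) & np.isfinite(marg) & profile.sampled
        m = marg[ok] - np.nanmin(marg[ok])
        p = profile.f_values[ok] - np.nanmin(profile.f_values[ok])
        assert np.max(np.abs(m - p)) < 0.2


class TestBootstrap:
    def test_resampling_disabled_gives_zero_errors(self):
        series = _double_well_series(n_windows=3, n=2000)
        err, _ = bootstrap_errors(series, n_boot=5, seed=0, resample=False)
        assert np.nanmax(err) < 1e-12  # identical replicates: zero spread

    def test_same_seed_identical_errors(self):
        series = _double_well_series(n_windows=3, n=2000)
        e1, _ = bootstrap_errors(series, n_boot=8, seed=5)
        e2, _ = bootstrap_errors(series, n_boot=8, seed=5)
        assert np.array_equal(np.nan_to_num(e1), np.nan_to_num(e2))

    def test_more_samples_reduce_median_error(self):
        # statistical contract checked over several independent seeds
        med_small, med_big = [], []
        for seed in range(10):
            small = _double_well_series(n_windows=5, n=1500, seed=1000 + 50 * seed)
            big = _double_well_series(n_windows=5, n=6000, seed=1000 + 50 * seed)
            es, _ = bootstrap_errors(small, n_boot=12, seed=seed)
            eb, _ = bootstrap_errors(big, n_boot=12, seed=seed)
            med_small.append(np.nanmedian(es))
            med_big.append(np.nanmedian(eb))
        assert np.median(med_big) < np.median(med_small)

    def test_block_longer_than_series_rejected(self):
        series = _double_well_series(n_windows=3, n=10)
        with pytest.raises(ValueError, match="block"):
            bootstrap_errors(series, n_boot=3, seed=0, block_fraction=2.0)

    def test_nboot_minimum(self):
        with pytest.raises(ValueError):
            bootstrap_errors(_double_well_series(n_windows=2, n=100),
                             n_boot=1, seed=0)


class TestCrossCheck:
    def test_iteration_agrees_with_ml_route(self):
        from ionfes.reference import ml_wham_1d

        series = _double_well_series(n_windows=7, n=5000)
        profile = wham_1d(series, n_bins=80)
        ref = ml_wham_1d(series, profile.bin_edges)
        both = profile.sampled & np.isfinite(ref)
        assert np.max(np.abs(profile.f_values[both] - ref[both])) < 0.05
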