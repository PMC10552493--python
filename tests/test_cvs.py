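"""Switching function, coordination numbers, angles and n(r) curves."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionfes.cvs import (CVSpec, SwitchingParams, chelate_angles,
                        coordination_number, partial_coordination_curve, switch,
                        switch_deriv)
from ionfes.potentials import DomainError

P612 = SwitchingParams(r0=5.0, n_exp=6, m_exp=12)


class TestSwitch:
    def test_exact_values(self):
        assert switch(0.0, P612) == 1.0
        # removable singularity at d = r0: limit n/m = 0.5 for (6, 12)
        assert switch(5.0, P612) == pytest.approx(0.5, abs=1e-9)
        assert switch(50.0, P612) < 1e-5

    def test_continuity_at_r0(self):
        lo = switch(5.0 * (1 - 1e-8), P612)
        hi = switch(5.0 * (1 + 1e-8), P612)
        assert lo == pytest.approx(0.5, abs=1e-6)
        assert hi == pytest.approx(0.5, abs=1e-6)

    @given(st.floats(0.0, 40.0), st.floats(0.5, 8.0))
    def test_weight_in_unit_interval(self, d, r0):
        s = switch(d, SwitchingParams(r0=r0))
        assert 0.0 < s <= 1.0

    @given(st.floats(0.01, 30.0), st.floats(0.01, 30.0))
    def test_strictly_decreasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        if hi - lo > 1e-9:
            assert switch(lo, P612) > switch(hi, P612)

    def test_matches_exact_rational_arithmetic(self, rng):
        # oracle: exact Fraction arithmetic away from the d = r0 pole
        p = SwitchingParams(r0=2.5, n_exp=6, m_exp=12)
        ds = rng.uniform(0.05, 12.0, size=1000)
        ds = ds[np.abs(ds - p.r0) > 1e-4]
        for d in ds:
            x = Fraction(d) / Fraction(5, 2)
            exact = (1 - x**6) / (1 - x**12)
            assert switch(float(d), p) == pytest.approx(float(exact), rel=1e-12)

    def test_derivative_matches_finite_difference(self):
        h = 1e-7
        for d in [0.3, 2.0, 4.999999, 5.0, 5.000001, 9.0]:
            fd = (switch(d + h, P612) - switch(d - h, P612)) / (2 * h)
            assert switch_deriv(d, P612) == pytest.approx(fd, abs=1e-5)

    def test_exponent_validation(self):
        with pytest.raises(ValueError):
            SwitchingParams(r0=5.0, n_exp=12, m_exp=6)


class TestCoordinationNumber:
    def _spec(self, n_members):
        return CVSpec(0, tuple(range(1, n_members + 1)), P612)

    def test_far_limit_is_zero(self):
        frame = np.vstack([[0, 0, 0], *[[50.0 + i, 0, 0] for i in range(6)]])
        value, _ = coordination_number(frame, self._spec(6))
        assert value < 6e-5

    def test_near_limit_counts_all_members(self):
        # six members at d = r0/10, spread in angle: CN ~ 6 like the fully
        # bound hexadentate pose
        angles = np.linspace(0, np.pi, 6)
        frame = np.vstack([[0, 0, 0],
                           *[[0.5 * np.cos(a), 0.5 * np.sin(a), 0.0]
                             for a in angles]])
        value, _ = coordination_number(frame, self._spec(6))
        assert value == pytest.approx(6.0, abs=6e-5)

    def test_half_near_half_far(self):
        frame = np.vstack([[0, 0, 0],
                           [0.4, 0, 0], [0, 0.4, 0], [0, 0, 0.4],
                           [60.0, 0, 0], [0, 60.0, 0], [0, 0, 60.0]])
        value, _ = coordination_number(frame, self._spec(6))
        assert value == pytest.approx(3.0, abs=1e-4)

    def test_gradient_matches_finite_difference(self, rng):
        frame = rng.uniform(-4, 4, size=(7, 3))
        frame[0] = 0.0
        spec = self._spec(6)
        _, grad = coordination_number(frame, spec)
        h = 1e-6
        for i in range(7):
            for d in range(3):
                fp = frame.copy()
                fm = frame.copy()
                fp[i, d] += h
                fm[i, d] -= h
                fd = (coordination_number(fp, spec)[0]
                      - coordination_number(fm, spec)[0]) / (2 * h)
                assert grad[i, d] == pytest.approx(fd, abs=1e-5)

    def test_gradients_sum_to_zero(self, rng):
        frame = rng.uniform(-4, 4, size=(5, 3))
        _, grad = coordination_number(frame, CVSpec(0, (1, 2, 3, 4), P612))
        assert np.allclose(grad.sum(axis=0), 0.0, atol=1e-12)

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        frame = rng.uniform(-4, 4, size=(5, 3))
        spec = CVSpec(0, (1, 2, 3, 4), P612)
        v0, _ = coordination_number(frame, spec)
        rot = Rotation.random(rng=123).as_matrix()
        v1, _ = coordination_number(frame @ rot.T + np.array([3.0, -1.0, 2.0]), spec)
        assert v1 == pytest.approx(v0, abs=1e-10)

    def test_coincident_member_rejected(self):
        frame = np.zeros((2, 3))
        with pytest.raises(DomainError):
            coordination_number(frame, CVSpec(0, (1,), P612))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CVSpec(0, (), P612)
        with pytest.raises(ValueError):
            CVSpec(0, (0, 1), P612)


class TestChelateAngles:
    def test_collinear_and_right_angle(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [1.0, 1.0, 0]])
        a = chelate_angles(frame, [(0, 1, 2), (0, 1, 3)])
        assert a[0] == pytest.approx(180.0)
        assert a[1] == pytest.approx(90.0)

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        frame = rng.uniform(-3, 3, size=(3, 3))
        a0 = chelate_angles(frame, [(0, 1, 2)])[0]
        rot = Rotation.random(rng=7).as_matrix()
        a1 = chelate_angles(frame @ rot.T + 5.0, [(0, 1, 2)])[0]
        assert a1 == pytest.approx(a0, abs=1e-9)

    def test_degenerate_arm_rejected(self):
        frame = np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(DomainError):
            chelate_angles(frame, [(0, 1, 2)])


class TestPartialCoordinationCurve:
    def test_direct_count(self):
        frame = np.array([[[0.0, 0, 0], [1.0, 0, 0], [0, 2.0, 0], [0, 0, 3.0]]])
        n = partial_coordination_curve(frame, 0, [1, 2, 3],
                                       np.array([1.5, 2.5, 3.5]))
        assert np.array_equal(n, [1.0, 2.0, 3.0])

    def test_all_zero_below_min_distance(self):
        frame = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])
        n = partial_coordination_curve(frame, 0, [1], np.array([1.0, 2.0]))
        assert np.array_equal(n, [0.0, 0.0])

    def test_mean_over_frames(self):
        f1 = np.array([[0.0, 0, 0], [1.0, 0, 0], [9.0, 0, 0]])
        f2 = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.5, 0, 0]])
        n = partial_coordination_curve(np.stack([f1, f2]), 0, [1, 2],
                                       np.array([2.0]))
        assert n[0] == pytest.approx(1.5)  # counts 1 and 2 average to 1.5

    def test_monotone_and_saturates(self, rng):
        traj = rng.uniform(-4, 4, size=(10, 8, 3))
        grid = np.linspace(0.0, 20.0, 40)
        n = partial_coordination_curve(traj, 0, list(range(1, 8)), grid)
        assert np.all(np.diff(n) >= 0)
        assert n[-1] == pytest.approx(7.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            partial_coordination_curve(np.empty((0, 3, 3)), 0, [1],
                                       np.array([1.0]))
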