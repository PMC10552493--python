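"""Pair potential, bonded terms, analytic forces and the umbrella bias."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionfes.potentials import (BondParams, DomainError, EnergyModel, OverlapError,
                               PairParams, ToySystem, bias_energy_force,
                               lj_124_from_well, pair_energy, pair_key,
                               total_energy_forces)


class TestPairEnergy:
    def test_zero_beyond_cutoff(self):
        p = PairParams(c12=1.0, c6=2.0, cutoff=5.0)
        assert pair_energy(5.0, p) == 0.0
        assert pair_energy(7.3, p) == 0.0

    def test_12_6_minimum_location_and_depth(self):
        # dU/dr = 0 at r* = (2 c12/c6)^(1/6) = 1 with U(r*) = -c6^2/(4 c12) = -1
        p = PairParams(c12=1.0, c6=2.0, cutoff=50.0)
        r = np.linspace(0.5, 3.0, 20001)
        u = pair_energy(r, p)
        i = np.argmin(u)
        assert r[i] == pytest.approx(1.0, abs=2e-4)
        assert u[i] == pytest.approx(-1.0, abs=1e-6)

    def test_pure_c4_term(self):
        p = PairParams(c12=1e-12, c4=1.0, cutoff=50.0)
        # c12 is negligible at r = 2: U = -c4/r^4 = -1/16
        assert pair_energy(2.0, p) == pytest.approx(-1.0 / 16.0, rel=1e-9)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(DomainError):
            pair_energy(0.0, PairParams(c12=1.0))
        with pytest.raises(DomainError):
            pair_energy(-1.0, PairParams(c12=1.0))

    def test_monotone_below_inner_minimum(self):
        p = lj_124_from_well(2.0, 4.0)
        r = np.linspace(0.5, 1.9, 200)
        u = pair_energy(r, p)
        assert np.all(np.diff(u) < 0)  # decreasing in r = increasing toward contact

    def test_collapse_guard(self):
        with pytest.raises(ValueError):
            PairParams(c12=0.0, c6=1.0)


class TestTotalEnergyForces:
    def test_noninteracting_beyond_cutoff(self):
        p = PairParams(c12=1.0, c6=2.0, cutoff=3.0)
        sys_ = ToySystem(positions=np.array([[0.0, 0, 0], [4.0, 0, 0]]),
                         roles=["ion", "ligand_oxygen"],
                         charges=np.zeros(2), masses=np.ones(2),
                         pair_table={pair_key("ion", "ligand_oxygen"): p})
        u, f = total_energy_forces(sys_)
        assert u == 0.0
        assert np.all(f == 0.0)

    def test_newtons_third_law(self, rng):
        # no tethers: with internal interactions only the net force vanishes
        sys_ = _random_five_particle_system(rng, tethers=False)
        _, f = total_energy_forces(sys_)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_forces_match_finite_differences(self, rng):
        h = 1e-6
        for _ in range(10):
            sys_ = _random_five_particle_system(rng)
            model = EnergyModel(sys_)
            u0, f = model.energy_forces(sys_.positions)
            for i in range(sys_.n_particles):
                for d in range(3):
                    xp = sys_.positions.copy()
                    xm = sys_.positions.copy()
                    xp[i, d] += h
                    xm[i, d] -= h
                    fd = -(model.energy_forces(xp)[0]
                           - model.energy_forces(xm)[0]) / (2 * h)
                    assert f[i, d] == pytest.approx(fd, abs=1e-5)

    def test_overlap_raises(self):
        p = PairParams(c12=1.0, cutoff=3.0)
        sys_ = ToySystem(positions=np.array([[0.0, 0, 0], [1e-5, 0, 0]]),
                         roles=["ion", "ligand_oxygen"],
                         charges=np.zeros(2), masses=np.ones(2),
                         pair_table={pair_key("ion", "ligand_oxygen"): p})
        with pytest.raises(OverlapError):
            total_energy_forces(sys_)


class TestBiasEnergyForce:
    def test_zero_at_center(self):
        g = np.ones((3, 3))
        e, f = bias_energy_force(2.5, g, center=2.5, k=20.0)
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_k20_unit_displacement_gives_10(self):
        # U = k/2 (s-s0)^2 with the production spring k = 20 kBT
        e, _ = bias_energy_force(3.0, np.zeros((1, 3)), center=2.0, k=20.0)
        assert e == pytest.approx(10.0)

    @given(st.floats(0.01, 3.0))
    def test_symmetric_about_center(self, delta):
        g = np.zeros((1, 3))
        ep, _ = bias_energy_force(2.0 + delta, g, 2.0, 20.0)
        em, _ = bias_energy_force(2.0 - delta, g, 2.0, 20.0)
        assert ep == pytest.approx(em, rel=1e-12)

    def test_force_direction(self):
        g = np.array([[1.0, 0.0, 0.0]])
        _, f = bias_energy_force(3.0, g, center=2.0, k=4.0)
        assert f[0, 0] == pytest.approx(-4.0)


class TestToySystemValidation:
    def test_requires_exactly_one_ion(self):
        with pytest.raises(ValueError, match="ion"):
            ToySystem(positions=np.zeros((2, 3)),
                      roles=["backbone", "backbone"],
                      charges=np.zeros(2), masses=np.ones(2))

    def test_rejects_self_bonds(self):
        with pytest.raises(ValueError, match="self-bond"):
            ToySystem(positions=np.zeros((2, 3)),
                      roles=["ion", "backbone"],
                      charges=np.zeros(2), masses=np.ones(2),
                      bonds=[(1, 1, BondParams(1.0, 1.0))])

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError, match="mass"):
            ToySystem(positions=np.zeros((2, 3)),
                      roles=["ion", "backbone"],
                      charges=np.zeros(2), masses=np.array([1.0, 0.0]))


def _random_five_particle_system(rng, tethers=True):
    from ionfes.potentials import BondParams

    positions = 4.0 * rng.standard_normal((5, 3))
    # keep particles apart so finite differences are well conditioned
    positions += np.arange(5)[:, None] * np.array([2.5, 0.0, 0.0])
    roles = ["ion", "ligand_oxygen", "ligand_oxygen", "backbone", "solvent_oxygen"]
    table = {
        pair_key("ion", "ligand_oxygen"): lj_124_from_well(2.0, 3.0, c4=2.0,
                                                           q_product=-1.0),
        pair_key("ion", "solvent_oxygen"): lj_124_from_well(2.2, 2.0),
        pair_key("ligand_oxygen", "ligand_oxygen"): PairParams(c12=10.0),
        pair_key("backbone", "solvent_oxygen"): PairParams(c12=5.0),
    }
    return ToySystem(positions=positions, roles=roles,
                     charges=rng.standard_normal(5), masses=np.ones(5),
                     bonds=[(1, 3, BondParams(k_bond=8.0, r_eq=1.2))],
                     pair_table=table,
                     tether_k=(np.array([0.0, 0.0, 0.3, 0.0, 0.2])
                               if tethers else np.zeros(5)),
                     tether_centers=np.zeros((5, 3)))
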