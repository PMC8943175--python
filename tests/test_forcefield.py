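"""Closed-form potential values, force-energy consistency, and the
equilibrium bond length of the FENE+WCA bond."""

import numpy as np
import pytest

import chromofold as cf
from chromofold.errors import PotentialDomainError


DEFAULTS = cf.ForceFieldParams()


class TestBondedPotential:
    @pytest.mark.parametrize(
        "r, expected",
        [
            # frozen from 30-digit evaluation of the closed form
            (10.0, 1726.0924347106856),
            (1.0, 16.018781308710862),
        ],
    )
    def test_closed_form_values(self, r, expected):
        assert cf.bonded_energy(r, DEFAULTS) == pytest.approx(expected, rel=1e-10)

    def test_diverges_at_maximum_extension(self):
        assert cf.bonded_energy(19.999999, DEFAULTS) > 5e4
        with pytest.raises(PotentialDomainError, match="FENE"):
            cf.bonded_energy(20.0, DEFAULTS)
        with pytest.raises(PotentialDomainError):
            cf.bonded_energy(-1.0, DEFAULTS)

    def test_force_zero_at_equilibrium_and_attractive_near_R0(self):
        # the equilibrium bond length prints as 0.99 sigma (two decimals);
        # the force is tiny at the true minimiser and small at the rounded value
        r_eq = cf.equilibrium_bond_length(DEFAULTS)
        assert abs(cf.bonded_force(r_eq, DEFAULTS)) < 1e-6
        assert abs(cf.bonded_force(0.99, DEFAULTS)) < 1.0
        assert cf.bonded_force(19.99, DEFAULTS) < -1e4

    def test_force_matches_finite_difference(self):
        h = 1e-6
        for r in (0.8, 1.05, 2.0, 10.0, 18.0):
            fd = -(cf.bonded_energy(r + h) - cf.bonded_energy(r - h)) / (2 * h)
            assert cf.bonded_force(r) == pytest.approx(fd, rel=1e-5)

    def test_strictly_convex_near_minimum(self):
        r = np.linspace(0.9, 1.1, 41)
        u = cf.bonded_energy(r)
        assert np.all(np.diff(u, 2) > 0)


class TestNonbondedPotential:
    def test_unit_separation_gives_unit_energy(self):
        assert cf.nonbonded_energy(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_cutoff_is_exactly_zero_and_continuous(self):
        cut = 2 ** (1 / 6)
        assert cf.nonbonded_energy(cut) == pytest.approx(0.0, abs=1e-10)
        for eps in (1e-8, -1e-8):
            assert abs(cf.nonbonded_energy(cut + eps)) < 1e-10
            assert abs(cf.nonbonded_force(cut + eps)) < 1e-5
        assert cf.nonbonded_energy(2.0) == 0.0
        assert cf.nonbonded_force(2.0) == 0.0

    def test_repulsive_core_value(self):
        # frozen from 30-digit evaluation
        assert cf.nonbonded_energy(0.9) == pytest.approx(7.636118953252916, rel=1e-10)

    def test_rejects_nonpositive_separation(self):
        with pytest.raises(PotentialDomainError):
            cf.nonbonded_energy(0.0)


class TestRestraintPotential:
    @pytest.mark.parametrize("r, expected", [(2.2, 0.0), (3.2, 1.0), (1.2, 1.0)])
    def test_harmonic_well(self, r, expected):
        assert cf.restraint_energy(r) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_about_rest_length(self):
        d = np.linspace(0.0, 2.0, 9)
        assert cf.restraint_energy(2.2 + d) == pytest.approx(cf.restraint_energy(2.2 - d))


class TestEquilibriumBondLength:
    def test_printed_parameters_give_0_99_sigma(self):
        assert round(cf.equilibrium_bond_length(DEFAULTS), 2) == 0.99

    def test_against_dense_grid_oracle(self):
        # brute-force grid minimisation at step 1e-5 sigma
        p = cf.ForceFieldParams(R0=1.5)
        r = np.arange(0.5, 2 ** (1 / 6), 1e-5)
        grid = r[np.argmin(cf.bonded_energy(r, p))]
        assert cf.equilibrium_bond_length(p) == pytest.approx(grid, abs=2e-5)
        assert round(cf.equilibrium_bond_length(p), 2) == 0.96

    def test_scales_linearly_with_sigma(self):
        base = cf.equilibrium_bond_length(DEFAULTS)
        for s in (0.5, 3.0):
            scaled = cf.equilibrium_bond_length(cf.ForceFieldParams(sigma=s))
            assert scaled == pytest.approx(s * base, rel=1e-8)

    def test_pure_fene_has_no_interior_minimum(self):
        # with the repulsive core off the bond energy is monotone increasing,
        # so the infimum sits at r -> 0 and root-finding must refuse
        p = cf.ForceFieldParams(epsilon_star=0.0)
        r = np.linspace(0.05, 1.1, 200)
        assert np.all(np.diff(cf.bonded_energy(r, p)) > 0)
        with pytest.raises(PotentialDomainError):
            cf.equilibrium_bond_length(p)


class TestSystemEnergyForces:
    def test_two_bonded_beads(self):
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        e, f = cf.system_energy_forces(pos)
        assert e == pytest.approx(16.018781308710862, rel=1e-10)
        assert np.allclose(f[0], -f[1])

    def test_single_bead_is_inert(self):
        e, f = cf.system_energy_forces(np.zeros((1, 3)))
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_forces_sum_to_zero_and_match_finite_differences(self, rng):
        for _ in range(12):
            n = int(rng.integers(3, 12))
            chain = cf.sarw_chain(n, seed=int(rng.integers(1 << 30)))
            restraints = None
            if n >= 5:
                restraints = cf.RestraintSet(np.array([[0, n - 1]]))
            e, f = cf.system_energy_forces(chain, restraints)
            assert np.abs(f.sum(axis=0)).max() < 1e-9
            h, scale = 1e-6, max(1.0, np.abs(f).max())
            for i in range(n):
                for d in range(3):
                    p = chain.positions.copy()
                    p[i, d] += h
                    ep, _ = cf.system_energy_forces(p, restraints)
                    p[i, d] -= 2 * h
                    em, _ = cf.system_energy_forces(p, restraints)
                    fd = -(ep - em) / (2 * h)
                    assert abs(f[i, d] - fd) / scale < 1e-5

    def test_broken_bond_is_identified(self):
        pos = np.zeros((3, 3))
        pos[1, 0] = 1.0
        pos[2, 0] = 25.0  # bond 1-2 beyond R0
        with pytest.raises(PotentialDomainError, match="bond 1-2"):
            cf.system_energy_forces(pos)

    def test_matches_mc_kernel_energies(self, rng):
        # the numba kernel duplicates the pair energies; hold them in lock-step
        from chromofold import _kernels

        for r in (0.7, 0.95, 1.05, 1.4, 5.0, 15.0):
            assert _kernels._bond_e(r, 30.0, 1.0, 1.0, 20.0) == pytest.approx(
                cf.bonded_energy(r), rel=1e-12
            )
        for r in (0.7, 0.95, 1.05, 1.3):
            assert _kernels._wca_e(r * r, 1.0, 1.0) == pytest.approx(
                cf.nonbonded_energy(r), abs=1e-12
            )
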