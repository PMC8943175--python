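"""Restraint selection, Monte Carlo satisfaction, and Langevin dynamics."""

import numpy as np
import pytest

import chromofold as cf
from chromofold.errors import ConfigError, ConvergenceError, InputFormatError
from chromofold.folding_engine import restraint_distances


def _hic(counts, bin_size=5000):
    return cf.HiCMatrix(chrom="chrS", bin_size=bin_size, counts=np.asarray(counts, float))


class TestSelectRestraints:
    def test_all_zero_matrix_gives_empty_set(self):
        rs = cf.select_restraints(_hic(np.zeros((10, 10))))
        assert len(rs) == 0

    def test_adjacent_contacts_are_excluded(self):
        m = np.zeros((6, 6))
        for i in range(5):
            m[i, i + 1] = m[i + 1, i] = 9.0
        assert len(cf.select_restraints(_hic(m))) == 0

    def test_top_quantile_on_toy_matrix(self):
        # counts {(0,2):5, (0,3):1, (1,3):3}; top half by count -> the two largest
        m = np.zeros((4, 4))
        m[0, 2] = m[2, 0] = 5
        m[0, 3] = m[3, 0] = 1
        m[1, 3] = m[3, 1] = 3
        rs = cf.select_restraints(_hic(m), rule="top_quantile:0.5")
        assert sorted(map(tuple, rs.pairs)) == [(0, 2), (1, 3)]

    def test_count_threshold(self):
        m = np.zeros((5, 5))
        m[0, 2] = m[2, 0] = 2
        m[0, 4] = m[4, 0] = 7
        rs = cf.select_restraints(_hic(m), rule="count_threshold:3")
        assert list(map(tuple, rs.pairs)) == [(0, 4)]

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((3, 3))
        m[0, 2] = 1.0  # mirror missing
        with pytest.raises(InputFormatError, match="symmetric"):
            _hic(m)

    def test_restraint_set_rejects_adjacent_and_duplicate_pairs(self):
        with pytest.raises(ConfigError):
            cf.RestraintSet(np.array([[0, 1]]))
        with pytest.raises(ConfigError):
            cf.RestraintSet(np.array([[0, 5], [0, 5]]))


class TestKineticTemperature:
    def test_zero_velocities(self):
        assert cf.kinetic_temperature(np.zeros((5, 3))) == 0.0

    def test_maxwell_boltzmann_sample(self, rng):
        v = rng.normal(0.0, 1.0, size=(10_000, 3))
        assert cf.kinetic_temperature(v) == pytest.approx(1.0, abs=0.03)

    def test_quadratic_in_velocity(self, rng):
        v = rng.normal(size=(50, 3))
        assert cf.kinetic_temperature(2 * v) == pytest.approx(
            4 * cf.kinetic_temperature(v)
        )


class TestMCFold:
    def test_empty_restraints_return_input_unchanged(self):
        chain = cf.sarw_chain(20, seed=0)
        out = cf.mc_fold(chain, cf.RestraintSet(np.zeros((0, 2))))
        assert np.array_equal(out.positions, chain.positions)

    def test_end_to_end_restraint_on_short_chain(self):
        chain = cf.sarw_chain(10, seed=3)
        rs = cf.RestraintSet(np.array([[0, 9]]))
        out = cf.mc_fold(chain, rs, cf.MCConfig(seed=5))
        d = restraint_distances(out.positions, rs)
        assert d[0] <= 2.2
        assert np.all(out.bond_lengths() < 20.0)

    def test_deterministic_under_fixed_seed(self):
        chain = cf.sarw_chain(30, seed=1)
        rs = cf.RestraintSet(np.array([[0, 15], [5, 25]]))
        a = cf.mc_fold(chain, rs, cf.MCConfig(seed=9))
        b = cf.mc_fold(chain, rs, cf.MCConfig(seed=9))
        assert np.array_equal(a.positions, b.positions)

    def test_unreachable_budget_raises_with_diagnostics(self):
        chain = cf.sarw_chain(60, seed=2)
        rs = cf.RestraintSet(np.array([[0, 59]]))
        ramp = cf.RestraintRamp(polish=False, n_stages=1)
        with pytest.raises(ConvergenceError, match="restrained pairs"):
            cf.mc_fold(chain, rs, cf.MCConfig(max_sweeps=2, seed=0, restraint_ramp=ramp))

    def test_out_of_range_restraint_rejected(self):
        chain = cf.sarw_chain(5, seed=0)
        with pytest.raises(ConfigError):
            cf.mc_fold(chain, cf.RestraintSet(np.array([[0, 10]])))


class TestLangevin:
    def test_zero_steps_leave_positions_unchanged(self):
        chain = cf.sarw_chain(10, seed=0)
        traj = cf.langevin_equilibrate(chain, None, cf.SimConfig(n_steps=0, seed=1))
        assert np.array_equal(traj.positions, chain.positions)

    def test_thermostat_short_run(self):
        # a longer, tighter version runs in the acceptance suite
        chain = cf.sarw_chain(50, seed=4)
        traj = cf.langevin_equilibrate(chain, None, cf.SimConfig(n_steps=20_000, seed=2))
        assert np.mean(traj.kinetic_temperatures[2000:]) == pytest.approx(1.0, abs=0.05)

    def test_energy_conservation_without_thermostat(self):
        # damping 0 turns the integrator into plain velocity Verlet
        chain = cf.sarw_chain(30, seed=3)
        cfg = cf.SimConfig(n_steps=1000, timestep=0.001, damping=0.0, seed=5)
        rng = np.random.default_rng(5)
        v0 = rng.normal(0.0, 1.0, (30, 3))  # same init the integrator draws
        traj = cf.langevin_equilibrate(chain, None, cfg)

        def etot(p, v):
            e, _ = cf.system_energy_forces(p)
            return e + 0.5 * np.sum(v**2)

        e0, e1 = etot(chain.positions, v0), etot(traj.positions, traj.velocities)
        assert abs(e1 - e0) / abs(e0) <= 1e-3

    def test_free_bead_diffuses_at_einstein_rate(self):
        # MSD per lag tau_lag is 6 T tau_lag / gamma for t >> m/gamma
        chain = cf.BeadChain(np.zeros((1, 3)))
        traj = cf.langevin_equilibrate(
            chain, None, cf.SimConfig(n_steps=100_000, seed=2, snapshot_stride=1000)
        )
        frames = np.asarray(traj.frames)  # spaced 10 tau
        inc = np.diff(frames[:, 0, :], axis=0)
        msd = np.mean(np.sum(inc**2, axis=1))
        assert msd == pytest.approx(60.0, rel=0.4)

    def test_deterministic_and_snapshot_stride(self):
        chain = cf.sarw_chain(12, seed=6)
        cfg = cf.SimConfig(n_steps=500, seed=7, snapshot_stride=100)
        a = cf.langevin_equilibrate(chain, None, cfg)
        b = cf.langevin_equilibrate(chain, None, cfg)
        assert np.array_equal(a.positions, b.positions)
        assert len(a.frames) == 6  # initial + 5 strided

    def test_unsatisfied_restraints_warn(self):
        chain = cf.sarw_chain(40, seed=1)
        rs = cf.RestraintSet(np.array([[0, 39]]))
        with pytest.warns(UserWarning, match="activation radius"):
            cf.langevin_equilibrate(chain, rs, cf.SimConfig(n_steps=1, seed=0))


class TestFoldChromosome:
    def test_restraint_free_run_stays_connected(self):
        hic = _hic(np.zeros((30, 30)))
        st = cf.fold_chromosome(hic, sim=cf.SimConfig(n_steps=200), seed=0)
        assert st.report["n_restraints"] == 0
        d = np.linalg.norm(np.diff(st.positions, axis=0), axis=1)
        assert np.all(d < 20.0)

    def test_same_seed_bit_identical(self, two_compartment):
        hic = two_compartment["hic"]
        mc = cf.MCConfig(max_sweeps=800)
        sim = cf.SimConfig(n_steps=300)
        a = cf.fold_chromosome(hic, mc=mc, sim=sim, seed=11)
        b = cf.fold_chromosome(hic, mc=mc, sim=sim, seed=11)
        assert np.array_equal(a.positions, b.positions)
        assert a.report == b.report

    def test_bin_count_mismatch_rejected(self, two_compartment):
        chain = cf.sarw_chain(7, seed=0)
        with pytest.raises(ConfigError, match="beads"):
            cf.fold_chromosome(two_compartment["hic"], chain=chain, seed=0)
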