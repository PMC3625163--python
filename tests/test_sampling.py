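"""Langevin dynamics, biased sampling, reweighting and T_f machinery."""

import numpy as np
import pytest

import foldmotif as fm
from foldmotif.sampling import (BiasSpec, SimulationConfig, Trajectory,
                                run_metropolis_1d)


class TestComputeQ:
    def test_native_is_one(self, toy_topology):
        assert fm.compute_Q(toy_topology, toy_topology.native_coords) == 1.0

    def test_extended_is_zero(self, hairpin_topology):
        assert fm.compute_Q(hairpin_topology,
                            fm.extended_chain(hairpin_topology)) == 0.0

    def test_counting_granularity(self, hairpin_topology):
        """Break all contacts but one: Q = 1/m exactly."""
        topo = hairpin_topology
        x = fm.extended_chain(topo)
        i, j = topo.contact_i[0], topo.contact_j[0]
        # fold the chain end back so exactly contact 0 re-forms
        x[j] = x[i] + [0.0, topo.contact_sigma[0], 0.0]
        assert fm.compute_Q(topo, x) == pytest.approx(1.0 / topo.n_contacts)


class TestRunLangevin:
    def test_seed_determinism(self, hairpin_topology):
        cfg = SimulationConfig(temperature=0.8, n_steps=20_000,
                               save_interval=50, seed=123)
        a = fm.run_langevin(hairpin_topology, cfg)
        b = fm.run_langevin(hairpin_topology, cfg)
        np.testing.assert_array_equal(a.q, b.q)
        np.testing.assert_array_equal(a.epot, b.epot)

    def test_nve_energy_conservation(self, dimer_topology):
        cfg = SimulationConfig(temperature=1.0, n_steps=10_000,
                               save_interval=10, seed=7, friction=0.0)
        tr = fm.run_langevin(dimer_topology, cfg)
        etot = tr.epot + tr.ekin
        assert etot.max() - etot.min() < 1e-4

    def test_equipartition(self, dimer_topology):
        """<KE> per degree of freedom = k_B T / 2 within 2%."""
        kes = []
        for seed in (7, 8):
            cfg = SimulationConfig(temperature=1.0, n_steps=1_000_000,
                                   save_interval=20, seed=seed, friction=10.0)
            tr = fm.run_langevin(dimer_topology, cfg)
            kes.append(tr.ekin.mean() / 6.0)
        assert np.mean(kes) == pytest.approx(0.5, rel=0.02)

    def test_harmonic_bond_variance(self, dimer_topology):
        """<(r - r0)^2> = k_B T / (2 K_r) within 3% (K_r (r-r0)^2 bond;
        averaged over a few 1e6-step runs for statistics)."""
        t = 1.0
        expected = t / (2.0 * dimer_topology.params.k_r)
        us = []
        for seed in (1, 2, 3, 4):
            cfg = SimulationConfig(temperature=t, n_steps=1_000_000,
                                   save_interval=20, seed=seed, friction=10.0)
            tr = fm.run_langevin(dimer_topology, cfg)
            # <U> = K_r <dr^2>
            us.append(tr.epot.mean() / dimer_topology.params.k_r)
        assert np.mean(us) == pytest.approx(expected, rel=0.03)

    def test_divergence_reported_with_step(self, hairpin_topology):
        cfg = SimulationConfig(temperature=1.0, n_steps=10_000,
                               save_interval=10, seed=0, timestep=0.2)
        with pytest.raises(RuntimeError, match="step"):
            fm.run_langevin(hairpin_topology, cfg)


class TestRunBiased:
    def test_zero_strength_equals_unbiased(self, hairpin_topology):
        cfg = SimulationConfig(temperature=0.9, n_steps=20_000,
                               save_interval=50, seed=5)
        plain = fm.run_langevin(hairpin_topology, cfg)
        nul = fm.run_biased(hairpin_topology, cfg,
                            BiasSpec("energy", 0.0, 10.0, 0.0))
        np.testing.assert_array_equal(plain.q, nul.q)
        np.testing.assert_array_equal(plain.epot, nul.epot)
        assert (nul.bias_values == 0).all()

    def test_stored_bias_matches_offline_recomputation(self, hairpin_topology):
        bias = BiasSpec("energy", center=-2.0, width=5.0, strength=3.0)
        cfg = SimulationConfig(temperature=0.9, n_steps=20_000,
                               save_interval=50, seed=5)
        tr = fm.run_biased(hairpin_topology, cfg, bias)
        np.testing.assert_allclose(tr.bias_values,
                                   bias.value(tr.epot, tr.q_smooth),
                                   rtol=1e-12)
        bias_q = BiasSpec("Q", center=0.5, width=0.2, strength=2.0)
        tr2 = fm.run_biased(hairpin_topology, cfg, bias_q)
        np.testing.assert_allclose(tr2.bias_values,
                                   bias_q.value(tr2.epot, tr2.q_smooth),
                                   rtol=1e-12)

    def test_bias_enhances_double_well_crossings(self, double_well):
        """Gaussian well at the 6 k_BT barrier top: crossings at least 5x
        more frequent than unbiased at equal chain length."""
        u, height = double_well

        def crossings(traj):
            state = 0
            count = 0
            for x in traj.q:
                if state <= 0 and x > 0.7:
                    count += 1
                    state = 1
                elif state >= 0 and x < 0.3:
                    count += 1
                    state = -1
            return count

        plain = run_metropolis_1d(u, 1.0, 200_000, seed=3)
        biased = run_metropolis_1d(
            u, 1.0, 200_000, seed=3,
            bias=BiasSpec("Q", center=0.5, width=0.12, strength=5.5))
        assert crossings(biased) >= 5 * max(crossings(plain), 1)


class TestReweight:
    def test_unbiased_run_gets_uniform_weights(self, hairpin_topology):
        cfg = SimulationConfig(temperature=0.9, n_steps=20_000,
                               save_interval=50, seed=2)
        tr = fm.run_langevin(hairpin_topology, cfg)
        sample = fm.reweight(tr, 0.9)
        np.testing.assert_allclose(sample.weights,
                                   1.0 / tr.n_frames, rtol=1e-10)
        assert sample.effective_sample_size == pytest.approx(tr.n_frames,
                                                             rel=1e-6)

    def test_biased_double_well_recovers_quadrature(self, double_well):
        """Reweighted biased sampling vs direct Boltzmann quadrature of the
        1-D potential: RMS deviation < 0.1 k_BT over the sampled range."""
        u, _ = double_well
        t = 1.0
        bias = BiasSpec("Q", center=0.5, width=0.15, strength=5.0)
        tr = run_metropolis_1d(u, t, 400_000, bias=bias, seed=11)
        sample = fm.reweight(tr, t)
        edges = np.linspace(0, 1, 41)
        hist, _ = np.histogram(sample.q, bins=edges, weights=sample.weights)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # quadrature oracle on the same bins
        xs = np.linspace(0, 1, 4001)
        boltz = np.exp(-u(xs) / t)
        ref = np.array([np.trapezoid(boltz[(xs >= a) & (xs < b)],
                                     xs[(xs >= a) & (xs < b)])
                        for a, b in zip(edges[:-1], edges[1:])])
        ref /= ref.sum()
        # adequately sampled bins only: fewer than ~100 frames in a bin
        # cannot resolve free energies at the 0.1 k_BT level
        neff, _ = np.histogram(sample.q, bins=edges)
        ok = (neff >= 100) & (ref > 0)
        f_est = -np.log(hist[ok])
        f_ref = -np.log(ref[ok])
        diff = f_est - f_ref
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff ** 2)) < 0.1

    def test_temperature_reweighting_harmonic_variance(self, dimer_topology):
        """Harmonic bond sampled at T and reweighted to 1.2 T: the bond
        energy matches the closed form <U> = k_B T' / 2 within 3%."""
        t, t2 = 1.0, 1.2
        us = []
        for seed in (3, 4, 5):
            cfg = SimulationConfig(temperature=t, n_steps=1_000_000,
                                   save_interval=20, seed=seed, friction=10.0)
            tr = fm.run_langevin(dimer_topology, cfg)
            sample = fm.reweight(tr, t2)
            us.append(float(np.sum(sample.weights * sample.energy)))
        assert np.mean(us) == pytest.approx(t2 / 2.0, rel=0.03)

    def test_low_ess_recorded(self, dimer_topology):
        cfg = SimulationConfig(temperature=1.0, n_steps=5_000,
                               save_interval=50, seed=1, friction=10.0)
        tr = fm.run_langevin(dimer_topology, cfg)
        with pytest.warns(UserWarning, match="effective sample size"):
            sample = fm.reweight(tr, 0.02)      # drastic extrapolation
        assert sample.messages

    def test_wham_pooling_consistent_with_single_run(self, double_well):
        """Two biased runs pooled by WHAM give the same profile as each
        alone where both sampled."""
        u, _ = double_well
        t = 1.0
        b1 = BiasSpec("Q", center=0.35, width=0.2, strength=4.0)
        b2 = BiasSpec("Q", center=0.65, width=0.2, strength=4.0)
        t1 = run_metropolis_1d(u, t, 150_000, bias=b1, seed=21)
        t2 = run_metropolis_1d(u, t, 150_000, bias=b2, seed=22)
        pooled = fm.reweight([t1, t2], t)
        single = fm.reweight(t1, t)
        edges = np.linspace(0, 1, 21)
        hp, _ = np.histogram(pooled.q, bins=edges, weights=pooled.weights)
        hs, _ = np.histogram(single.q, bins=edges, weights=single.weights)
        ok = (hp > 1e-4) & (hs > 1e-4)
        fp = -np.log(hp[ok])
        fs = -np.log(hs[ok])
        assert np.std((fp - fs) - (fp - fs).mean()) < 0.15


class TestTrajectoryInvariants:
    def test_q_in_unit_interval_everywhere(self, toy_tf):
        q = np.concatenate([t.q for t in toy_tf.trajectories])
        assert (q >= 0).all() and (q <= 1).all()

    def test_invalid_q_rejected(self):
        cfg = SimulationConfig(temperature=1.0, n_steps=100, save_interval=10)
        with pytest.raises(ValueError, match="Q"):
            Trajectory(config=cfg, steps=np.arange(10), epot=np.zeros(10),
                       ekin=np.zeros(10), q=np.full(10, 1.5),
                       q_smooth=np.zeros(10), bias_values=np.zeros(10))


class TestEstimateTf:
    def test_populations_balanced_at_tf(self, toy_tf):
        """Definition self-check: at the returned T_f the folded population
        is one half."""
        assert abs(toy_tf.p_folded - 0.5) < 0.02

    def test_tf_scales_linearly_with_epsilon(self, toy_tf, toy_tf_scaled):
        """The Hamiltonian is linear in the energy scale, so scaling all
        epsilon-type constants by 1.5 scales T_f by exactly 1.5 (the
        estimate is covariant in reduced units)."""
        ratio = toy_tf_scaled.kbtf_kcal_per_mol / toy_tf.kbtf_kcal_per_mol
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_barrier_crossings_recorded(self, toy_tf):
        assert toy_tf.diagnostics["n_barrier_crossings"] >= 20
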