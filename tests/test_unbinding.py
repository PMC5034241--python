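import warnings

import numpy as np
import pytest

from dimerlink import (
    CaChain,
    DecayFitError,
    DimerStructure,
    EntanglementTrace,
    SimConfig,
    fit_decay,
    gaussian_entanglement,
    run_unbinding,
    wca_force,
    wca_potential,
)
import dimerlink.unbinding as ub
from conftest import random_open_coil, ring_dimer

CUTOFF = 2.0 ** (1.0 / 6.0)


class TestWca:
    def test_force_vanishes_at_the_potential_minimum(self):
        f = wca_force(np.array([CUTOFF, 0.0, 0.0]))
        np.testing.assert_allclose(f, 0.0, atol=1e-12)
        assert wca_potential(CUTOFF) == 0.0
        assert wca_potential(1.5 * CUTOFF) == 0.0

    def test_potential_at_sigma_equals_epsilon(self):
        assert wca_potential(1.0, sigma=1.0, epsilon=1.0) == pytest.approx(1.0)
        assert wca_potential(2.53, sigma=2.53, epsilon=3.0) == pytest.approx(3.0)

    def test_repulsive_inside_cutoff(self):
        r_vec = np.array([0.0, 0.99 * CUTOFF, 0.0])
        f = wca_force(r_vec)
        assert f @ r_vec > 0  # pushes the bead away

    def test_overlap_is_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            f = wca_force(np.array([1e-4, 0.0, 0.0]))
        assert np.isfinite(f).all()

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            wca_force(np.zeros(3))


class TestSimConfig:
    def test_bond_rest_must_be_one_and_a_half_sigma(self):
        with pytest.raises(ValueError):
            SimConfig(sigma=1.0, bond_rest=1.2)
        SimConfig(sigma=2.0, bond_rest=3.0)  # consistent pair accepted

    def test_fit_window_must_exist(self):
        with pytest.raises(ValueError):
            SimConfig(t_max=10.0, dt=0.01, record_every=100)


class TestIntegrator:
    def test_free_diffusion_msd(self):
        """With all interactions off each bead diffuses with D = kT/γ.

        MSD(t) = 6·D·t at t >> m/γ; at t = 100 τ_sim the residual
        inertial correction is under 1%.
        """
        nb, dt = 3000, 0.01
        rng = np.random.default_rng(99)
        pos = np.zeros((nb, 3))
        vel = rng.standard_normal((nb, 3))
        cid = np.zeros(nb, dtype=np.int64)
        ou_d = np.exp(-dt)
        ou_n = np.sqrt(1.0 - ou_d**2)
        for _ in range(20):
            noise = rng.standard_normal((500, nb, 3))
            ub._advance(pos, vel, cid, noise, dt, 1.0, ou_d, ou_n,
                        300.0, 1.5, 1.0, 1.0, False)
        t = 20 * 500 * dt
        msd = float(np.mean(np.sum(pos**2, axis=1)))
        assert msd == pytest.approx(6.0 * t, rel=0.05)

    def test_bonds_stay_within_twenty_percent(self, unbinding_trace):
        """Recorded configurations keep every bond near its rest length."""
        dimer, trace, cfg = unbinding_trace
        pos, cid, n_a = ub._initial_positions(dimer, cfg)
        rng = np.random.default_rng(7)
        vel = rng.standard_normal(pos.shape)
        ou_d = np.exp(-cfg.gamma * cfg.dt / cfg.mass)
        ou_n = np.sqrt(cfg.epsilon * (1 - ou_d**2) / cfg.mass)
        worst = 0.0
        for _ in range(60):
            noise = rng.standard_normal((200, pos.shape[0], 3))
            ub._advance(pos, vel, cid, noise, cfg.dt, cfg.mass, ou_d, ou_n,
                        cfg.spring_k, cfg.bond_rest, cfg.sigma, cfg.epsilon, True)
            for lo, hi in ((0, n_a), (n_a, pos.shape[0])):
                bonds = np.linalg.norm(np.diff(pos[lo:hi], axis=0), axis=1)
                worst = max(worst, float(np.max(np.abs(bonds - cfg.bond_rest))))
        assert worst < 0.2 * cfg.bond_rest


class TestRunUnbinding:
    def test_trace_starts_at_the_static_entanglement(self, unbinding_trace):
        dimer, trace, _ = unbinding_trace
        static = gaussian_entanglement(dimer.chain_a, dimer.chain_b)
        assert trace.g_prime_mean[0] == pytest.approx(static, abs=1e-9)
        assert np.all(trace.g_prime_traj[:, 0] == trace.g_prime_traj[0, 0])

    def test_entanglement_decays_to_zero(self, unbinding_trace):
        _, trace, _ = unbinding_trace
        tail = trace.g_prime_mean[-len(trace.g_prime_mean) // 10:]
        assert np.all(np.abs(tail) < 0.1)

    def test_times_strictly_increasing(self, unbinding_trace):
        _, trace, _ = unbinding_trace
        assert np.all(np.diff(trace.times) > 0)
        assert trace.times.size == trace.g_prime_mean.size == trace.g_prime_sem.size

    def test_pre_separated_chains_stay_unentangled(self):
        a = CaChain("A", random_open_coil(25, seed=31))
        b = CaChain("B", random_open_coil(25, seed=32, origin=(500.0, 0.0, 0.0)))
        dimer = DimerStructure("FAR", a, b)
        cfg = SimConfig(n_traj=2, t_max=60.0, dt=0.01, record_every=50, seed=5)
        trace = run_unbinding(dimer, cfg)
        assert np.all(np.abs(trace.g_prime_mean) < 0.05)

    def test_independent_master_seeds_agree(self):
        """Two ensembles from different master seeds sample the same decay."""
        dimer = ring_dimer(50)
        traces = []
        for seed in (100, 4200):
            cfg = SimConfig(n_traj=16, t_max=250.0, dt=0.01, record_every=50, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traces.append(run_unbinding(dimer, cfg))
        t1, t2 = traces
        sem = np.sqrt(t1.g_prime_sem**2 + t2.g_prime_sem**2)
        z = np.abs(t1.g_prime_mean[1:] - t2.g_prime_mean[1:]) / np.maximum(sem[1:], 1e-12)
        assert np.all(z < 4.0)


class TestFitDecay:
    @staticmethod
    def _planted_trace(a0=-1.5, tau0=900.0, n_traj=40, n_rec=1100, dt_rec=5.0, seed=8):
        rng = np.random.default_rng(seed)
        t = dt_rec * np.arange(n_rec)
        clean = a0 * np.exp(-t / tau0)
        traj = clean[None, :] + 0.25 * rng.standard_normal((n_traj, n_rec))
        return EntanglementTrace(
            times=t,
            g_prime_mean=traj.mean(axis=0),
            g_prime_sem=traj.std(axis=0, ddof=1) / np.sqrt(n_traj),
            g_prime_traj=traj,
        )

    def test_recovers_planted_exponential_within_bootstrap_errors(self):
        trace = self._planted_trace()
        fit = fit_decay(trace, skip=100)
        assert abs(fit.g_star - (-1.5)) < 3 * fit.g_star_err
        assert abs(fit.tau - 900.0) < 3 * fit.tau_err
        assert fit.tau > 0 and fit.fit_start_index == 100

    def test_pure_zero_trace_is_rejected(self):
        n_traj, n_rec = 10, 300
        traj = np.zeros((n_traj, n_rec))
        trace = EntanglementTrace(
            times=5.0 * np.arange(n_rec),
            g_prime_mean=traj.mean(axis=0),
            g_prime_sem=traj.std(axis=0, ddof=1) / np.sqrt(n_traj),
            g_prime_traj=traj,
        )
        with pytest.raises(DecayFitError):
            fit_decay(trace, skip=100)

    def test_short_trace_rejected(self):
        trace = self._planted_trace(n_rec=105)
        with pytest.raises(DecayFitError):
            fit_decay(trace, skip=100)

    def test_simulated_decay_fits_with_negative_amplitude(self, unbinding_trace):
        _, trace, _ = unbinding_trace
        fit = fit_decay(trace, skip=100)
        assert fit.g_star < 0  # the cut-Hopf dimer is negatively entangled
        assert fit.tau > 0


class TestTauGrowsWithChainLength:
    @staticmethod
    def _bootstrap_taus(trace, skip, n_boot, seed):
        """Refit tau on trajectory resamples (test-side, independent of fit_decay)."""
        from scipy.optimize import curve_fit

        t = trace.times[skip:]
        traj = trace.g_prime_traj[:, skip:]
        rng = np.random.default_rng(seed)
        taus = []
        for _ in range(n_boot):
            idx = rng.integers(0, traj.shape[0], traj.shape[0])
            y = traj[idx].mean(axis=0)
            try:
                popt, _ = curve_fit(
                    lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
                    p0=[y[0], (t[-1] - t[0]) / 3],
                    bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=10000,
                )
                taus.append(popt[1])
            except RuntimeError:
                continue
        return np.asarray(taus)

    def test_longer_chains_disentangle_more_slowly(self):
        """Disentanglement time grows with chain length (Rouse-like trend)."""
        runs = {}
        for n, n_traj, t_max, rec, seed in (
            (50, 8, 800.0, 50, 77),
            (100, 12, 2500.0, 125, 78),
        ):
            cfg = SimConfig(n_traj=n_traj, t_max=t_max, dt=0.01,
                            record_every=rec, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                runs[n] = run_unbinding(ring_dimer(n), cfg)
        fit_small = fit_decay(runs[50], skip=100, seed=1)
        fit_big = fit_decay(runs[100], skip=100, seed=1)
        assert fit_small.tau < fit_big.tau
        # paired bootstrap: tau ordering holds with >= 95% confidence
        b_small = self._bootstrap_taus(runs[50], 100, 200, seed=10)
        b_big = self._bootstrap_taus(runs[100], 100, 200, seed=11)
        m = min(b_small.size, b_big.size)
        assert np.mean(b_small[:m] < b_big[:m]) >= 0.95
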