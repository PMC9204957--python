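import numpy as np
import pytest

from commensim import (
    ColonizerPool,
    LifeHistory,
    SDEConfig,
    covariance_matrix,
    drift_vector,
    euler_maruyama_step,
    noise_factor,
    sample_host_lifespan,
    simulate_host_sde,
)
from commensim._kernels import advance_host
from commensim.diffusion import DriftDiffusion, simulate_xo_batch


class TestDrift:
    def test_empty_host_no_migration(self, pool2):
        lh = LifeHistory(m=0.0, tau=0.0, alpha0=0.5, N=100, H=2)
        np.testing.assert_allclose(drift_vector((0.0, 0.0), lh, pool2), 0.0)

    def test_empty_host_full_migration(self, pool2):
        # only the fill events are active with x0 = 1
        lh = LifeHistory(m=1.0, tau=0.0, alpha0=0.5, N=100, H=2)
        A = drift_vector((0.0, 0.0), lh, pool2)
        assert A[0] == pytest.approx(pool2.p[0] / lh.N)
        assert A[1] == pytest.approx((1.0 - pool2.p[0]) / lh.N)

    def test_matches_discrete_oracle(self, pool2):
        # empirical mean one-step change of the jump process
        lh = LifeHistory(m=0.05, tau=0.0, alpha0=0.8, N=50, H=2)
        start = np.array([10, 15], dtype=np.int64)
        rng = np.random.default_rng(21)
        R = 200_000
        deltas = np.zeros((R, 2))
        p = np.ascontiguousarray(pool2.p)
        for r in range(R):
            c = start.copy()
            advance_host(c, np.int64(1), lh.m, lh.alpha0, p, 50.0, rng)
            deltas[r] = (c - start) / 50.0
        A = drift_vector((0.2, 0.3), lh, pool2)
        se = deltas.std(axis=0, ddof=1) / np.sqrt(R)
        assert np.all(np.abs(deltas.mean(axis=0) - A) < 4.0 * se)


class TestCovariance:
    def test_empty_host_no_migration_zero(self, pool2):
        lh = LifeHistory(m=0.0, tau=0.0, alpha0=0.5, N=100, H=2)
        np.testing.assert_allclose(
            covariance_matrix((0.0, 0.0), lh, pool2), 0.0
        )

    def test_full_focal_occupancy_bernoulli(self, pool2):
        # x = 1: only the focal-replacement event fires, a Bernoulli jump
        lh = LifeHistory(m=0.4, tau=0.0, alpha0=0.0, N=100, H=2)
        q = lh.m * (1.0 - pool2.p[0])
        V = covariance_matrix((1.0, 0.0), lh, pool2)
        assert V[0, 0] == pytest.approx(q * (1.0 - q) / lh.N**2)

    def test_matches_discrete_oracle(self, pool2):
        lh = LifeHistory(m=0.05, tau=0.0, alpha0=0.8, N=50, H=2)
        start = np.array([10, 15], dtype=np.int64)
        rng = np.random.default_rng(22)
        R = 200_000
        deltas = np.zeros((R, 2))
        p = np.ascontiguousarray(pool2.p)
        for r in range(R):
            c = start.copy()
            advance_host(c, np.int64(1), lh.m, lh.alpha0, p, 50.0, rng)
            deltas[r] = (c - start) / 50.0
        V = covariance_matrix((0.2, 0.3), lh, pool2)
        emp = np.cov(deltas.T)
        # moment-based standard errors of the sample (co)variances
        centered = deltas - deltas.mean(axis=0)
        for i in range(2):
            for j in range(2):
                prod = centered[:, i] * centered[:, j]
                se = prod.std(ddof=1) / np.sqrt(R)
                assert abs(emp[i, j] - V[i, j]) < 4.0 * se


class TestNoiseFactor:
    def test_zero(self):
        np.testing.assert_array_equal(noise_factor(np.zeros((2, 2))), 0.0)

    def test_scaled_identity(self):
        B = noise_factor(np.eye(2) * 4.0)
        np.testing.assert_allclose(B, np.eye(2) * 2.0)

    def test_random_psd_reconstruction(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            X = rng.normal(size=(2, 2))
            V = X @ X.T
            B = noise_factor(V)
            np.testing.assert_allclose(B.T @ B, V, atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            noise_factor(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            noise_factor(np.array([[-1e-3, 0.0], [0.0, 1.0]]))

    def test_tiny_negative_floored(self):
        B = noise_factor(np.diag([-1e-13, 1.0]))
        np.testing.assert_allclose(B.T @ B, np.diag([0.0, 1.0]), atol=1e-10)


class TestEulerMaruyama:
    def test_no_drift_no_noise_is_identity(self, rng):
        dd = DriftDiffusion(A=np.zeros(2), V=np.zeros((2, 2)),
                            Bfac=np.zeros((2, 2)))
        out = euler_maruyama_step((0.3, 0.4), dd, SDEConfig(dt=1.0), rng)
        np.testing.assert_allclose(out, [0.3, 0.4])

    def test_pure_drift_deterministic(self, rng):
        dd = DriftDiffusion(A=np.array([0.01, -0.02]), V=np.zeros((2, 2)),
                            Bfac=np.zeros((2, 2)))
        out = euler_maruyama_step((0.3, 0.4), dd, SDEConfig(dt=2.0), rng)
        np.testing.assert_allclose(out, [0.32, 0.36])

    def test_boundary_clipping(self, rng):
        dd = DriftDiffusion(A=np.array([-1.0, 2.0]), V=np.zeros((2, 2)),
                            Bfac=np.zeros((2, 2)))
        out = euler_maruyama_step((0.3, 0.4), dd, SDEConfig(dt=1.0), rng)
        assert out[0] == 0.0
        assert out.sum() <= 1.0


class TestLifespan:
    def test_mean(self):
        rng = np.random.default_rng(4)
        draws = np.array([sample_host_lifespan(1e-4, rng) for _ in range(100_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 1e4) < 4 * se

    def test_median_survival(self):
        rng = np.random.default_rng(5)
        tau = 0.01
        draws = np.array([sample_host_lifespan(tau, rng) for _ in range(20_000)])
        surviving = (draws > np.log(2.0) / tau).mean()
        assert surviving == pytest.approx(0.5, abs=0.02)

    def test_tau_one_mean_one(self):
        rng = np.random.default_rng(6)
        draws = np.array([sample_host_lifespan(1.0, rng) for _ in range(50_000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.02)

    def test_immortal(self, rng):
        assert sample_host_lifespan(0.0, rng) == np.inf


class TestSimulateSDE:
    def test_t_end_zero(self, rng, pool2, lh_small):
        traj = simulate_host_sde(
            (0.1, 0.2), lh_small, pool2, SDEConfig(), rng, t_end=0.0
        )
        assert traj.times.shape == (1,)
        np.testing.assert_allclose(traj.xo[0], [0.1, 0.2])

    def test_same_seed_bit_identical(self, pool2, lh_small):
        a = simulate_host_sde((0.1, 0.2), lh_small, pool2, SDEConfig(),
                              np.random.default_rng(42), t_end=200)
        b = simulate_host_sde((0.1, 0.2), lh_small, pool2, SDEConfig(),
                              np.random.default_rng(42), t_end=200)
        np.testing.assert_array_equal(a.xo, b.xo)

    def test_absorbing_empty_state_without_migration(self, pool2):
        lh = LifeHistory(m=0.0, tau=0.0, alpha0=0.0, N=100, H=2)
        traj = simulate_host_sde((0.0, 0.0), lh, pool2, SDEConfig(),
                                 np.random.default_rng(1), t_end=100)
        np.testing.assert_array_equal(traj.xo, 0.0)

    def test_stationary_mean_matches_pool(self, pool2):
        # tau=0, alpha0=0, m=1: long-run mean focal frequency -> p_i
        lh = LifeHistory(m=1.0, tau=0.0, alpha0=0.0, N=200, H=2)
        rng = np.random.default_rng(11)
        R = 300
        out = simulate_xo_batch(
            np.zeros((R, 2)), lh, pool2, SDEConfig(), rng,
            checkpoints=np.array([6000.0]),
        )
        x = out[0, :, 0]
        se = x.std(ddof=1) / np.sqrt(R)
        assert abs(x.mean() - pool2.p[0]) < 4 * se

    def test_batch_matches_single_trajectory_stats(self, pool2):
        # the vectorised batch integrator and the scalar path agree
        lh = LifeHistory(m=0.05, tau=0.0, alpha0=0.5, N=100, H=2)
        R, t_end = 150, 300
        singles = np.array(
            [
                simulate_host_sde(
                    (0.2, 0.3), lh, pool2, SDEConfig(),
                    np.random.default_rng(1000 + i), t_end=t_end,
                    record_every=t_end,
                ).xo[-1]
                for i in range(R)
            ]
        )
        batch = simulate_xo_batch(
            np.tile([0.2, 0.3], (R, 1)), lh, pool2, SDEConfig(),
            np.random.default_rng(55), checkpoints=np.array([float(t_end)]),
        )[0]
        for comp in range(2):
            se = np.hypot(
                singles[:, comp].std(ddof=1) / np.sqrt(R),
                batch[:, comp].std(ddof=1) / np.sqrt(R),
            )
            assert abs(singles[:, comp].mean() - batch[:, comp].mean()) < 4 * se

    def test_dt_robustness(self, pool2):
        # halving dt shifts checkpoint means by less than the MC error
        lh = LifeHistory(m=0.05, tau=0.0, alpha0=0.5, N=100, H=2)
        R = 400
        means = {}
        for dt in (1.0, 0.5):
            out = simulate_xo_batch(
                np.tile([0.2, 0.3], (R, 1)), lh, pool2, SDEConfig(dt=dt),
                np.random.default_rng(7), checkpoints=np.array([400.0]),
            )[0]
            means[dt] = (out.mean(axis=0), out.std(axis=0, ddof=1) / np.sqrt(R))
        diff = np.abs(means[1.0][0] - means[0.5][0])
        mc_err = np.hypot(means[1.0][1], means[0.5][1])
        assert np.all(diff < 4.0 * mc_err)
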