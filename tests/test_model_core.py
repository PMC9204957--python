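import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commensim import (
    ColonizerPool,
    HostState,
    LifeHistory,
    event_distribution_multitaxon,
    simulate_host_discrete,
    step_discrete,
    transition_probabilities,
)
from commensim.model_core import _transitions_xo

from conftest import make_state


class TestLifeHistory:
    def test_valid(self):
        lh = LifeHistory(m=0.5, tau=0.1, alpha0=2.0, N=100, H=5)
        assert lh.N == 100

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(m=-0.1, tau=0.1, alpha0=0.0, N=10, H=2),
            dict(m=1.1, tau=0.1, alpha0=0.0, N=10, H=2),
            dict(m=0.1, tau=2.0, alpha0=0.0, N=10, H=2),
            dict(m=0.1, tau=0.1, alpha0=-1.0, N=10, H=2),
            dict(m=0.1, tau=0.1, alpha0=0.0, N=0, H=2),
            dict(m=0.1, tau=0.1, alpha0=0.0, N=10, H=1),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            LifeHistory(**kwargs)


class TestColonizerPool:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ColonizerPool(p=np.array([0.3, 0.3]))

    def test_lineage_taxon_allowed(self):
        pool = ColonizerPool(p=np.array([0.0, 1.0]))
        assert pool.p[0] == 0.0

    def test_bounds(self):
        with pytest.raises(ValueError):
            ColonizerPool(p=np.array([-0.1, 1.1]))


class TestHostState:
    def test_counts_to_freqs(self):
        s = make_state([200, 300], N=1000)
        assert s.load == pytest.approx(0.5)
        assert s.x0 == pytest.approx(0.5)
        assert s.projection(0) == (pytest.approx(0.2), pytest.approx(0.3))

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            make_state([600, 600], N=1000)

    def test_exactly_one_representation(self):
        with pytest.raises(ValueError):
            HostState(N=10, counts=np.array([1]), freqs=np.array([0.1]))


class TestTransitionProbabilities:
    def test_empty_host_no_migration_absorbing(self):
        lh = LifeHistory(m=0.0, tau=0.2, alpha0=1.5, N=100, H=2)
        pool = ColonizerPool(p=np.array([0.3, 0.7]))
        ts = transition_probabilities((0.0, 0.0), lh, pool, 0)
        for name in ("t_xm_op", "t_xp_om", "t_op", "t_xp", "t_xm", "t_om"):
            assert getattr(ts, name) == 0.0
        assert ts.t_stay == pytest.approx(1.0 - lh.tau)
        assert ts.total() == pytest.approx(1.0)

    def test_full_focal_occupancy(self):
        m, p_i, tau = 0.3, 0.1, 0.05
        lh = LifeHistory(m=m, tau=tau, alpha0=0.7, N=100, H=2)
        pool = ColonizerPool(p=np.array([p_i, 1 - p_i]))
        ts = transition_probabilities((1.0, 0.0), lh, pool, 0)
        assert ts.t_xm_op == pytest.approx((1 - tau) * m * (1 - p_i))
        assert ts.t_op == ts.t_xp == ts.t_xm == ts.t_om == 0.0

    def test_hand_evaluated_interior_state(self):
        # x=0.2, o=0.3, m=0.01, p=0.1, alpha0=1, tau=1e-4 evaluated by hand
        lh = LifeHistory(m=0.01, tau=1e-4, alpha0=1.0, N=1000, H=2)
        pool = ColonizerPool(p=np.array([0.1, 0.9]))
        ts = transition_probabilities((0.2, 0.3), lh, pool, 0)
        assert ts.t_xm_op == pytest.approx(0.06119388, abs=1e-10)
        assert ts.t_xp_om == pytest.approx(
            0.9999 * 0.3 * (0.01 * 0.1 + 0.99 * 0.2), abs=1e-12
        )
        assert ts.t_xm == pytest.approx(0.9999 * 0.2 * 0.99 * 0.5, abs=1e-12)
        assert ts.total() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_state_rejected(self):
        lh = LifeHistory(m=0.1, tau=0.0, alpha0=0.0, N=10, H=2)
        pool = ColonizerPool(p=np.array([1.0]))
        with pytest.raises(ValueError):
            transition_probabilities((0.7, 0.5), lh, pool, 0)

    @given(
        x=st.floats(0.0, 1.0),
        o=st.floats(0.0, 1.0),
        m=st.floats(0.0, 1.0),
        tau=st.floats(0.0, 1.0),
        alpha0=st.floats(0.0, 5.0),
        p_i=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_property(self, x, o, m, tau, alpha0, p_i):
        if x + o > 1.0:
            x, o = x / (x + o), o / (x + o)
        lh = LifeHistory(m=m, tau=tau, alpha0=alpha0, N=100, H=2)
        pool = ColonizerPool(p=np.array([p_i, 1.0 - p_i]))
        ts = transition_probabilities((x, o), lh, pool, 0)
        arr = ts.as_array()
        assert np.all(arr >= -1e-12)
        assert ts.total() == pytest.approx(1.0, abs=1e-9)


class TestEventDistributionMultitaxon:
    def test_two_taxon_marginal_is_projection(self, lh_small, pool2):
        state = make_state([200, 300], N=1000)
        ed = event_distribution_multitaxon(state, lh_small, pool2)
        ts = transition_probabilities(state, lh_small, pool2, 0)
        np.testing.assert_allclose(
            ed.marginal(0, lh_small).as_array(), ts.as_array(), atol=1e-12
        )

    def test_three_taxon_normalization(self, lh_small):
        pool = ColonizerPool(p=np.array([0.5, 0.3, 0.2]))
        state = make_state([100, 200, 300], N=1000)
        ed = event_distribution_multitaxon(state, lh_small, pool)
        assert ed.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ed.probs >= -1e-12)

    def test_three_taxon_pooled_equals_two_taxon(self, lh_small):
        # brute-force marginalization: taxon 0 vs pooled {1, 2}
        pool3 = ColonizerPool(p=np.array([0.5, 0.3, 0.2]))
        state3 = make_state([100, 200, 300], N=1000)
        ed = event_distribution_multitaxon(state3, lh_small, pool3)
        marg = ed.marginal(0, lh_small)
        x, o = state3.projection(0)
        p_pooled = ColonizerPool(p=np.array([0.5, 0.5]))
        direct = transition_probabilities((x, o), lh_small, p_pooled, 0)
        np.testing.assert_allclose(
            marg.as_array(), direct.as_array(), atol=1e-12
        )

    @given(
        n1=st.integers(0, 40),
        n2=st.integers(0, 40),
        n3=st.integers(0, 20),
        m=st.floats(0.0, 1.0),
        alpha0=st.floats(0.0, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_projection_consistency_property(self, n1, n2, n3, m, alpha0):
        lh = LifeHistory(m=m, tau=0.01, alpha0=alpha0, N=100, H=2)
        pool = ColonizerPool(p=np.array([0.2, 0.5, 0.3]))
        state = make_state([n1, n2, n3], N=100)
        ed = event_distribution_multitaxon(state, lh, pool)
        assert ed.probs.sum() == pytest.approx(1.0, abs=1e-10)
        for taxon in range(3):
            ts = transition_probabilities(state, lh, pool, taxon)
            np.testing.assert_allclose(
                ed.marginal(taxon, lh).as_array(), ts.as_array(), atol=1e-12
            )


class TestStepDiscrete:
    def test_empty_host_without_migration_is_frozen(self, rng):
        lh = LifeHistory(m=0.0, tau=0.0, alpha0=0.0, N=100, H=2)
        pool = ColonizerPool(p=np.array([1.0]))
        state = HostState.empty(1, 100)
        for _ in range(20):
            state, died = step_discrete(state, lh, pool, rng)
            assert not died
            assert state.counts[0] == 0

    def test_tau_one_always_dies(self, rng, pool2):
        lh = LifeHistory(m=0.5, tau=1.0, alpha0=0.0, N=100, H=2)
        state = make_state([10, 10], N=100)
        for _ in range(10):
            _, died = step_discrete(state, lh, pool2, rng)
            assert died

    def test_one_step_conservation(self, rng, lh_small, pool2):
        state = make_state([200, 300], N=1000)
        for _ in range(300):
            new, died = step_discrete(state, lh_small, pool2, rng)
            if died:
                continue
            diff = int(new.counts.sum()) - int(state.counts.sum())
            assert diff in (-1, 0, 1)
            assert np.all(new.counts >= 0)
            assert new.counts.sum() <= 1000
            state = new

    def test_empirical_one_step_frequencies(self, pool2):
        # Monte Carlo one-step change frequencies vs analytic probabilities
        lh = LifeHistory(m=0.2, tau=0.02, alpha0=0.7, N=50, H=2)
        state = make_state([10, 15], N=50)
        ed = event_distribution_multitaxon(state, lh, pool2)
        expected = {}
        for kind, pr, d in zip(ed.kinds, ed.probs, ed.deltas):
            key = ("death",) if kind[0] == "hostdeath" else tuple(d)
            expected[key] = expected.get(key, 0.0) + pr
        rng = np.random.default_rng(777)
        n = 100_000
        observed = {k: 0 for k in expected}
        for _ in range(n):
            new, died = step_discrete(state, lh, pool2, rng)
            key = ("death",) if died else tuple(new.counts - state.counts)
            observed[key] += 1
        for key, pr in expected.items():
            if pr == 0.0:
                assert observed[key] == 0
                continue
            se = np.sqrt(pr * (1.0 - pr) / n)
            assert abs(observed[key] / n - pr) < 4.0 * se, key


class TestSimulateHostDiscrete:
    def test_max_steps_guard(self, rng, lh_small, pool2):
        with pytest.raises(ValueError):
            simulate_host_discrete(
                HostState.empty(2, 1000), lh_small, pool2, rng, max_steps=0
            )

    def test_single_step_recorded(self, rng, pool2):
        lh = LifeHistory(m=1.0, tau=0.0, alpha0=0.0, N=100, H=2)
        traj = simulate_host_discrete(
            HostState.empty(2, 100), lh, pool2, rng, max_steps=1
        )
        assert list(traj.times) == [0, 1]
        assert traj.counts.shape == (2, 2)

    def test_stationary_mean_matches_pool(self, pool2):
        # tau=0, alpha0=0, m=1: stationary within-host frequency -> p_i.
        # Single long run; the standard error comes from batch means.
        lh = LifeHistory(m=1.0, tau=0.0, alpha0=0.0, N=200, H=2)
        rng = np.random.default_rng(99)
        burn = 10 * 200 * 6
        traj = simulate_host_discrete(
            HostState.empty(2, 200), lh, pool2, rng,
            max_steps=burn + 120_000, record_every=100,
        )
        samples = traj.counts[traj.times > burn, 0] / 200.0
        batches = np.array_split(samples, 40)
        means = np.array([b.mean() for b in batches])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - pool2.p[0]) < 4.0 * se

    def test_extinction_when_alpha0_above_one_without_migration(self, pool2):
        lh = LifeHistory(m=0.0, tau=0.0, alpha0=2.0, N=200, H=2)
        rng = np.random.default_rng(5)
        for _ in range(20):
            traj = simulate_host_discrete(
                make_state([90, 90], N=200), lh, pool2, rng,
                max_steps=200 * 100, record_every=200 * 100,
            )
            assert traj.counts[-1].sum() == 0

    def test_death_terminates_recording(self, pool2):
        lh = LifeHistory(m=0.01, tau=0.5, alpha0=0.0, N=100, H=2)
        rng = np.random.default_rng(8)
        traj = simulate_host_discrete(
            HostState.empty(2, 100), lh, pool2, rng, max_steps=10_000
        )
        assert traj.death_step is not None
        assert traj.times[-1] <= traj.death_step
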