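"""Unit and property tests for the Kalman value learning and boost policy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmlsim.agent import (
    BoostState,
    KalmanTable,
    ValueEstimate,
    boost_cost,
    compute_dv,
    compute_neuromodulation,
    kalman_update,
    softmax_probs,
    surprise,
    trial_type_surprise,
)
from rmlsim.config import AgentConfig


def scalar_kalman_reference(mean0, var0, obs_noise, outcomes):
    """Independent textbook scalar Kalman recursion (the oracle)."""
    m, v = mean0, var0
    for z in outcomes:
        k = v / (v + obs_noise)
        m = m + k * (z - m)
        v = (1 - k) * v
    return m, v


class TestKalmanUpdate:
    def test_zero_prediction_error_leaves_mean(self):
        est = ValueEstimate(mean=5.0, uncertainty=3.7, observation_noise=1.0)
        assert kalman_update(est, outcome=5.0).mean == pytest.approx(5.0)

    def test_noise_free_observation_is_fully_trusted(self):
        est = ValueEstimate(mean=1.0, uncertainty=4.0, observation_noise=0.0)
        assert kalman_update(est, outcome=9.0).mean == pytest.approx(9.0)

    def test_convergence_to_stationary_reward(self):
        # diffuse prior: 50 observations of a constant reward pin the mean
        est = ValueEstimate(mean=0.0, uncertainty=1e4, observation_noise=1.0)
        for _ in range(50):
            est = kalman_update(est, outcome=7.0)
        assert est.mean == pytest.approx(7.0, abs=1e-3)
        m_ref, _ = scalar_kalman_reference(0.0, 1e4, 1.0, [7.0] * 50)
        assert est.mean == pytest.approx(m_ref, abs=1e-12)

    @given(
        mean0=st.floats(-10, 10),
        var0=st.floats(0.01, 50),
        noise=st.floats(0.01, 10),
        outcomes=st.lists(st.floats(-10, 10), min_size=1, max_size=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_recursion(self, mean0, var0, noise, outcomes):
        est = ValueEstimate(mean=mean0, uncertainty=var0, observation_noise=noise)
        for z in outcomes:
            est = kalman_update(est, z)
        m_ref, v_ref = scalar_kalman_reference(mean0, var0, noise, outcomes)
        assert est.mean == pytest.approx(m_ref, abs=1e-10)
        assert est.uncertainty == pytest.approx(v_ref, abs=1e-10)

    @given(
        var0=st.floats(0, 50),
        noise=st.floats(0.01, 10),
        outcome=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_uncertainty_never_increases_without_process_noise(
        self, var0, noise, outcome
    ):
        est = ValueEstimate(mean=0.0, uncertainty=var0, observation_noise=noise)
        new = kalman_update(est, outcome)
        assert new.uncertainty <= est.uncertainty + 1e-12
        assert new.uncertainty >= 0

    def test_table_matches_scalar_route(self):
        rng = np.random.default_rng(0)
        outcomes = rng.normal(3, 2, size=20)
        table = KalmanTable(n=1, prior_mean=0.0, prior_var=9.0, obs_noise=2.0)
        est = ValueEstimate(mean=0.0, uncertainty=9.0, observation_noise=2.0)
        for z in outcomes:
            table.update(0, z)
            est = kalman_update(est, z)
        assert table.means[0] == pytest.approx(est.mean, abs=1e-10)
        assert table.uncertainties[0] == pytest.approx(est.uncertainty, abs=1e-10)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            ValueEstimate(mean=0.0, uncertainty=-1.0, observation_noise=1.0)
        est = ValueEstimate(mean=0.0, uncertainty=1.0, observation_noise=1.0)
        with pytest.raises(ValueError):
            kalman_update(est, outcome=np.nan)


class TestSurprise:
    def test_zero_for_confirmed_expectation(self):
        assert surprise(5.0, 5.0) == 0.0

    @given(m=st.floats(-50, 50), d=st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_of_absolute_prediction_error(self, m, d):
        assert surprise(m, m + d) == pytest.approx(surprise(m, m - d))
        assert surprise(m, m + d) >= 0

    def test_trial_type_surprise_symmetric_extremes(self):
        # 6x6 grid of rewards 2..7: the mean trial total is 9 by enumeration
        sums = [l + r for l in range(2, 8) for r in range(2, 8)]
        mean_total = np.mean(sums)
        assert mean_total == pytest.approx(9.0)
        assert trial_type_surprise(4, mean_total) == pytest.approx(5.0)
        assert trial_type_surprise(14, mean_total) == pytest.approx(5.0)
        assert trial_type_surprise(9, mean_total) == 0.0

    def test_trial_type_surprise_monotone_in_deviation(self):
        values = [trial_type_surprise(s, 9.0) for s in range(4, 15)]
        deviations = [abs(s - 9) for s in range(4, 15)]
        assert values == deviations


class TestBoostPolicy:
    def make_state(self, **kwargs) -> BoostState:
        cfg = AgentConfig(**kwargs)
        bs = BoostState(cfg)
        bs.register_state("s")
        return bs

    def test_softmax_matches_hand_evaluation(self):
        probs = softmax_probs(np.array([1.0, 2.0, 4.0]), temperature=1.0)
        expected = np.exp([1.0, 2.0, 4.0])
        expected /= expected.sum()
        assert probs == pytest.approx(expected, abs=1e-12)

    def test_near_greedy_limit(self):
        bs = self.make_state(n_boost_levels=5, boost_temperature=0.01)
        bs._table("s").means[:] = [0, 0, 0, 0, 5.0]
        rng = np.random.default_rng(1)
        picks = [bs.select_boost("s", rng)[1] for _ in range(200)]
        assert np.mean(np.array(picks) == 4) > 0.99

    def test_uniform_when_q_values_tie(self):
        bs = self.make_state(n_boost_levels=4, boost_temperature=0.5)
        bs._table("s").means[:] = 2.0
        rng = np.random.default_rng(2)
        n = 10_000
        picks = np.array([bs.select_boost("s", rng)[1] for _ in range(n)])
        freqs = np.bincount(picks, minlength=4) / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_unregistered_state_raises(self):
        bs = self.make_state()
        with pytest.raises(KeyError):
            bs.select_boost("unknown", np.random.default_rng(0))

    def test_generalization_keeps_update_centered(self):
        # the chosen level moves most; neighbors move monotonically less
        bs = self.make_state(n_boost_levels=10, boost_generalization=1.5,
                             q_prior_mean=0.0, q_prior_var=4.0)
        bs.update("s", 4, net_outcome=10.0)
        shifts = bs.q_means("s")
        assert np.argmax(shifts) == 4
        assert np.all(np.diff(shifts[:5]) > 0) and np.all(np.diff(shifts[4:]) < 0)

    def test_boost_rationality(self):
        """No reward gain from boost -> lowest level; large gain -> highest."""
        rng = np.random.default_rng(3)
        for gain, expect_high in [(0.0, False), (3.0, True)]:
            bs = self.make_state(
                n_boost_levels=10, boost_temperature=0.05, cost_rate=0.1,
                q_prior_mean=10.0, q_prior_var=25.0,
            )
            for _ in range(400):
                level, idx = bs.select_boost("s", rng)
                frac = (level - 1.0) / 9.0
                reward = 5.0 + gain * frac + 0.2 * rng.standard_normal()
                bs.update("s", idx, reward - bs.cost(level))
            mean_level = bs.selection_probs("s") @ bs.levels
            if expect_high:
                assert mean_level > 7.5
            else:
                assert mean_level < 3.5


class TestCostAndNeuromodulation:
    def test_cost_linear_through_origin(self):
        assert boost_cost(0.0, 0.19) == 0.0
        assert boost_cost(4.0, 0.19) == pytest.approx(2 * boost_cost(2.0, 0.19))
        with pytest.raises(ValueError):
            boost_cost(-1.0, 0.19)

    def test_neuromodulation_anchors_and_bounds(self):
        cfg = AgentConfig()
        lo = compute_neuromodulation(cfg.boost_min, cfg)
        assert lo.lc == pytest.approx(cfg.lc_min)
        assert lo.vta == pytest.approx(cfg.vta_base)
        hi = compute_neuromodulation(cfg.boost_max, cfg)
        assert hi.lc == pytest.approx(cfg.lc_max)
        with pytest.raises(ValueError):
            compute_neuromodulation(cfg.boost_max + 1, cfg)

    def test_neuromodulation_monotone_and_matches_affine_table(self):
        cfg = AgentConfig(vta_coeff=0.5)
        levels = np.linspace(cfg.boost_min, cfg.boost_max, 10)
        lcs = [compute_neuromodulation(b, cfg).lc for b in levels]
        vtas = [compute_neuromodulation(b, cfg).vta for b in levels]
        assert np.all(np.diff(lcs) >= 0) and np.all(np.diff(vtas) >= 0)
        # independent tabulation from the config coefficients
        frac = (levels - cfg.boost_min) / (cfg.boost_max - cfg.boost_min)
        assert lcs == pytest.approx(cfg.lc_min + frac * (cfg.lc_max - cfg.lc_min))
        assert vtas == pytest.approx(np.clip(1.0 + 0.5 * frac, cfg.vta_min, cfg.vta_max))


class TestValueDifference:
    def make(self, mean):
        return ValueEstimate(mean=mean, uncertainty=0.1, observation_noise=1.0)

    def test_zero_for_equal_means_and_antisymmetry(self):
        a, b = self.make(3.3), self.make(5.1)
        assert compute_dv(a, a) == 0.0
        assert compute_dv(a, b) == -compute_dv(b, a)

    def test_pretrained_grid_extremes(self):
        # Kalman pretraining on stationary rewards recovers the +/-5 extreme
        table = KalmanTable(n=2, prior_mean=4.5, prior_var=25.0, obs_noise=1.0)
        for _ in range(30):
            table.update([0, 1], [7.0, 2.0])
        dv = table.means[0] - table.means[1]
        assert dv == pytest.approx(5.0, abs=0.05)
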