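"""Agent mechanics: values, exploration bonus, choice rule, learning updates."""

import types

import numpy as np
import pytest
from scipy.stats import norm

from slowrl.agents import (
    KalmanFALearner,
    RandomKeyAgent,
    WSLSAgent,
    accept_value,
    make_agent,
    measurement_noise,
    p_accept,
    resolve_block_params,
    stimulus_value,
)
from slowrl.circular import encode_feature
from slowrl.simulate import simulate_choices

from oracles import TabularKalman


def _spec(condition):
    return types.SimpleNamespace(condition=condition)


class TestValueComputation:
    def test_zero_weights_give_zero_value(self):
        basis = np.concatenate([encode_feature(10, 5, 15), encode_feature(200, 5, 15)])
        assert stimulus_value(np.zeros(30), basis) == 0.0

    def test_uniform_weights_expose_two_dimension_summation(self):
        """With w = 50 everywhere and each dimension's basis summing to 1,
        the two dimensions each contribute 50."""
        basis = np.concatenate([encode_feature(10, 5, 15), encode_feature(200, 5, 15)])
        assert stimulus_value(np.full(30, 50.0), basis) == pytest.approx(100.0)

    def test_one_hot_reads_single_weight(self):
        basis = np.zeros(30)
        basis[7] = 1.0
        w = np.zeros(30)
        w[7] = 80.0
        assert stimulus_value(w, basis) == pytest.approx(80.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stimulus_value(np.zeros(30), np.zeros(31))


class TestAcceptValueAndChoice:
    def test_block_start_bonus(self, base_params):
        """At block start U is 5 per feature, so V_a = 50 + c * 10."""
        agent = KalmanFALearner("1LR", base_params)
        agent.start_block(_spec("slow"))
        x = agent._basis(33.0, 190.0)
        vals, uncs = agent._value_and_uncertainty(x)
        assert vals.sum() == pytest.approx(50.0)
        assert uncs.sum() == pytest.approx(10.0)
        assert accept_value(vals.sum(), uncs.sum(), 6.0) == pytest.approx(110.0)

    def test_zero_exploration_weight(self):
        assert accept_value(62.0, 10.0, 0.0) == 62.0

    @pytest.mark.parametrize("sigma", [1.0, 10.0, 42.0])
    def test_indifference_point(self, sigma):
        assert p_accept(50.0, sigma) == pytest.approx(0.5)

    def test_one_sigma_above_reject_value(self):
        assert p_accept(50.0 + 7.0, 7.0) == pytest.approx(norm.cdf(1.0), abs=1e-12)

    def test_saturation(self):
        assert p_accept(1e9, 10.0) == pytest.approx(1.0, abs=1e-9)
        assert p_accept(-1e9, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_accept_value(self):
        vas = np.linspace(0, 100, 50)
        ps = [p_accept(v, 20.0) for v in vas]
        assert np.all(np.diff(ps) > 0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            p_accept(50.0, 0.0)


class TestMeasurementNoise:
    def test_half_rate(self):
        # U = 5 with M = 5 gives the next learning rate 0.5
        assert measurement_noise(0.5) == pytest.approx(5.0)

    def test_inversion_example(self):
        # alpha = 0.8 at U0 = 5 requires M = 5 * 0.2 / 0.8 = 1.25
        assert measurement_noise(0.8) == pytest.approx(1.25)

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 0.62, 0.99])
    def test_roundtrip_first_trial_rate(self, alpha):
        m = measurement_noise(alpha)
        assert 5.0 / (5.0 + m) == pytest.approx(alpha)

    def test_closed_ends(self):
        assert measurement_noise(0.0) == np.inf
        assert measurement_noise(1.0) == 0.0
        with pytest.raises(ValueError):
            measurement_noise(1.5)


class TestLearningUpdate:
    def test_full_step_tabular_limit(self):
        """One-hot basis, alpha = 1, weights zeroed: the touched weight jumps
        to the full outcome."""
        agent = KalmanFALearner("1LR", dict(kappa=1000.0, c=0.0, sigma=10.0, alpha=1.0))
        agent.start_block(_spec("slow"))
        agent.w[:] = 0.0
        agent.update(48.0, 120.0, "accept", 100.0)
        assert agent.w[0, 2] == pytest.approx(100.0, abs=1e-10)  # node at 48 degrees
        assert agent.w[1, 5] == pytest.approx(100.0, abs=1e-10)  # node at 120 degrees

    def test_no_update_on_reject_or_none(self, base_params):
        agent = KalmanFALearner("1LR", base_params)
        agent.start_block(_spec("slow"))
        w0, v0, a0 = agent.w.copy(), agent.v.copy(), agent.alpha.copy()
        agent.update(48.0, 120.0, "reject", 50.0)
        agent.update(48.0, 120.0, "none", np.nan)
        assert np.array_equal(agent.w, w0)
        assert np.array_equal(agent.v, v0)
        assert np.array_equal(agent.alpha, a0)

    def test_variance_shrinks_and_stays_nonnegative(self, base_params):
        agent = KalmanFALearner("1LR", base_params)
        agent.start_block(_spec("slow"))
        rng = np.random.default_rng(1)
        for _ in range(40):
            s, f = rng.uniform(0, 360, 2)
            v_before = agent.v.copy()
            agent.update(s, f, "accept", rng.uniform(0, 100))
            assert np.all(agent.v <= v_before + 1e-12)
            assert np.all(agent.v >= 0.0)

    def test_uncertainty_and_rate_decay_on_repeated_stimulus(self, base_params):
        """Stationary world: repeatedly accepting the same stimulus drives the
        exploration bonus toward zero and the learning rate down."""
        agent = KalmanFALearner("1LR", base_params)
        agent.start_block(_spec("slow"))
        us, alphas = [], []
        for _ in range(80):
            x = agent._basis(48.0, 120.0)
            _, uncs = agent._value_and_uncertainty(x)
            us.append(float(uncs.sum()))
            alphas.append(float(agent.alpha[0]))
            agent.update(48.0, 120.0, "accept", 80.0)
        # the bonus contracts toward zero (slowly in the basis tails)
        assert us[-1] < 1.0 < us[0] / 5.0
        assert np.all(np.diff(us) <= 1e-12)
        assert np.all(np.diff(alphas) <= 1e-12)
        assert alphas[0] == pytest.approx(base_params["alpha"])


class TestSlotResolution:
    def test_4lr_slots(self):
        params = dict(kappa=5, c=1, sigma=10, alpha_SR=0.8, alpha_FR=0.7, alpha_SI=0.4, alpha_FI=0.3)
        slow = resolve_block_params("4LR", params, _spec("slow"))
        assert (slow.alpha_s0, slow.alpha_f0) == (0.8, 0.3)  # slow relevant, fast irrelevant
        assert not slow.mean_update
        fast = resolve_block_params("4LR", params, _spec("fast"))
        assert (fast.alpha_s0, fast.alpha_f0) == (0.4, 0.7)

    def test_2lrc_shares_block_rate_with_mean_update(self):
        params = dict(kappa=5, c=1, sigma=10, alpha_S=0.6, alpha_F=0.2)
        slow = resolve_block_params("2LRc", params, _spec("slow"))
        assert slow.alpha_s0 == slow.alpha_f0 == 0.6
        assert slow.mean_update
        fast = resolve_block_params("2LRc", params, _spec("fast"))
        assert fast.alpha_s0 == fast.alpha_f0 == 0.2

    def test_condition_varying_controls(self):
        p1 = dict(kappa=5, c_slow=2.0, c_fast=8.0, sigma=10, alpha=0.5)
        assert resolve_block_params("1LRc", p1, _spec("slow")).c == 2.0
        assert resolve_block_params("1LRc", p1, _spec("fast")).c == 8.0
        p2 = dict(kappa=5, c=1, sigma_slow=20.0, sigma_fast=60.0, alpha=0.5)
        assert resolve_block_params("1LRsigma2", p2, _spec("slow")).sigma == 20.0
        assert resolve_block_params("1LRsigma2", p2, _spec("fast")).sigma == 60.0


class TestNestedModelEquivalences:
    """Tied-rate models collapse onto their nested siblings.

    Exact collapses pair models with the same learning-rate propagation:
    4LR and 2LRf both update rates per feature; 2LRc and 1LR both use the
    mean uncertainty.  Across the two groups the collapse additionally
    requires the two per-feature uncertainties to coincide, which holds for
    a uniform (kappa = 0) basis.
    """

    def test_4lr_tied_equals_2lrf(self, session):
        p4 = dict(kappa=6, c=6, sigma=42, alpha_SR=0.7, alpha_FR=0.3, alpha_SI=0.7, alpha_FI=0.3)
        p2 = dict(kappa=6, c=6, sigma=42, alpha_S=0.7, alpha_F=0.3)
        log4 = simulate_choices("4LR", p4, session, 5)
        log2 = simulate_choices("2LRf", p2, session, 5)
        assert log4.drop(columns=["participant"]).equals(log2.drop(columns=["participant"]))

    def test_2lrc_tied_equals_1lr(self, session):
        pc = dict(kappa=6, c=6, sigma=42, alpha_S=0.55, alpha_F=0.55)
        p1 = dict(kappa=6, c=6, sigma=42, alpha=0.55)
        logc = simulate_choices("2LRc", pc, session, 5)
        log1 = simulate_choices("1LR", p1, session, 5)
        assert logc.drop(columns=["participant"]).equals(log1.drop(columns=["participant"]))

    def test_4lr_tied_equals_1lr_with_uniform_basis(self, session):
        """With kappa = 0 the per-feature uncertainties are identical, so the
        per-feature and mean rate updates coincide."""
        p4 = dict(kappa=0.0, c=6, sigma=42, alpha_SR=0.5, alpha_FR=0.5, alpha_SI=0.5, alpha_FI=0.5)
        p1 = dict(kappa=0.0, c=6, sigma=42, alpha=0.5)
        log4 = simulate_choices("4LR", p4, session, 5)
        log1 = simulate_choices("1LR", p1, session, 5)
        assert log4.drop(columns=["participant"]).equals(log1.drop(columns=["participant"]))


class TestTabularOracle:
    @pytest.mark.parametrize("mean_update", [True, False])
    def test_trajectory_matches_independent_tabular_filter(self, mean_update):
        """Scripted 5-trial block with (numerically) one-hot bases: the
        function-approximation learner reduces to a per-position tabular
        Kalman filter; V, U, alpha, w and v must agree to 1e-10."""
        model = "1LR" if mean_update else "2LRf"
        params = (
            dict(kappa=2000.0, c=3.0, sigma=25.0, alpha=0.7)
            if mean_update
            else dict(kappa=2000.0, c=3.0, sigma=25.0, alpha_S=0.7, alpha_F=0.4)
        )
        agent = KalmanFALearner(model, params, node_count=15)
        agent.start_block(_spec("slow"))
        bp = resolve_block_params(model, params, _spec("slow"))
        oracle = TabularKalman(
            bp.alpha_s0, bp.alpha_f0, bp.m_s, bp.m_f, bp.mean_update, bp.c, bp.sigma
        )
        script = [  # (slow angle, fast angle, reward) on the 24-degree node grid
            (0.0, 96.0, 80.0),
            (24.0, 240.0, 60.0),
            (0.0, 48.0, 30.0),
            (336.0, 96.0, 90.0),
            (24.0, 312.0, 55.0),
        ]
        for s, f, r in script:
            x = agent._basis(s, f)
            vals, uncs = agent._value_and_uncertainty(x)
            assert vals.sum() == pytest.approx(oracle.value(s, f), abs=1e-10)
            assert uncs[0] == pytest.approx(oracle.uncertainty(s, f)[0], abs=1e-10)
            assert uncs[1] == pytest.approx(oracle.uncertainty(s, f)[1], abs=1e-10)
            assert agent.accept_prob(s, f) == pytest.approx(oracle.accept_prob(s, f), abs=1e-10)
            assert agent.alpha[0] == pytest.approx(oracle.alpha[0], abs=1e-10)
            assert agent.alpha[1] == pytest.approx(oracle.alpha[1], abs=1e-10)
            agent.update(s, f, "accept", r)
            oracle.learn(s, f, r)
        # full state comparison after the script
        for dim in range(2):
            for node, angle in enumerate(np.arange(15) * 24.0):
                assert agent.w[dim, node] == pytest.approx(oracle._v(dim, angle), abs=1e-10)
                assert agent.v[dim, node] == pytest.approx(oracle._var(dim, angle), abs=1e-10)


class TestControlModels:
    def test_wsls_rule(self):
        agent = WSLSAgent(dict(epsilon=0.1))
        agent.start_block(None)
        assert agent.accept_prob(0, 0) == 0.5  # first choice random
        agent.update(0, 0, "accept", 60.0)
        assert agent.accept_prob(0, 0) == pytest.approx(0.9)  # win: R >= 50
        agent.update(0, 0, "accept", 40.0)
        assert agent.accept_prob(0, 0) == pytest.approx(0.1)  # loss
        agent.update(0, 0, "reject", 50.0)
        assert agent.accept_prob(0, 0) == pytest.approx(0.1)  # after reject: switch with eps
        agent.update(0, 0, "accept", 50.0)
        assert agent.accept_prob(0, 0) == pytest.approx(0.9)  # R = 50 counts as win

    def test_random_key_bias(self):
        agent = RandomKeyAgent(dict(b_r=0.7))
        assert agent.accept_prob(0, 0, accept_key=1) == pytest.approx(0.7)
        assert agent.accept_prob(0, 0, accept_key=0) == pytest.approx(0.3)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            WSLSAgent(dict(epsilon=1.2))
        with pytest.raises(ValueError):
            make_agent("random_choice", dict(b_a=-0.1))

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            make_agent("5LR", {})

    def test_bandit_ignores_features(self, session):
        """The bandit's accept probability is the same whatever the stimulus."""
        agent = make_agent("bandit", dict(c=4.0, sigma=30.0, alpha=0.5))
        agent.start_block(_spec("slow"))
        p1 = agent.accept_prob(0.0, 0.0)
        p2 = agent.accept_prob(123.0, 271.0)
        assert p1 == p2
        assert agent.test_values((0, 0), (90, 90)) == (0.0, 0.0)
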