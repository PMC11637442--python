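"""Task generator: rewards, sequences, counterbalancing, environment."""

import numpy as np
import pytest

from slowrl.circular import circular_distance
from slowrl.task import (
    SessionConfig,
    build_session,
    clairvoyant_gain,
    generate_fast_sequence,
    generate_slow_sequence,
    generate_test_pairs,
    reward_of,
    run_environment,
)

GRID = np.arange(15) * 24.0


def steps(seq):
    d = np.abs(np.diff(seq))
    return np.minimum(d, 360.0 - d)


@pytest.mark.parametrize(
    "angle, maxpos, expected",
    [(100, 100, 100.0), (0, 180, 0.0), (10, 100, 50.0), (280, 10, 50.0)],
)
def test_reward_examples(angle, maxpos, expected):
    assert reward_of(angle, maxpos) == pytest.approx(expected)


def test_reward_linear_in_circular_distance():
    for a in np.arange(0, 360, 7.5):
        d = circular_distance(a, 190.0)
        assert reward_of(a, 190.0) == pytest.approx((180.0 - d) / 180.0 * 100.0)


class TestSlowSequence:
    def test_balance_and_length(self, rng):
        seq = generate_slow_sequence(GRID, 4, 30.0, rng)
        assert len(seq) == 60
        vals, counts = np.unique(seq, return_counts=True)
        assert len(vals) == 15 and np.all(counts == 4)
        # once per cycle of 15
        for c in range(4):
            assert len(set(seq[c * 15 : (c + 1) * 15])) == 15

    def test_reproducible_given_seed(self):
        a = generate_slow_sequence(GRID, 4, 30.0, np.random.default_rng(5))
        b = generate_slow_sequence(GRID, 4, 30.0, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_tiny_sd_walk_stays_local(self):
        """With a vanishing step size the walk snaps to nearest unused
        neighbours; mean steps stay below two grid spacings."""
        mean_steps = [
            steps(generate_slow_sequence(GRID, 1, 1e-6, np.random.default_rng(s))).mean()
            for s in range(50)
        ]
        assert np.mean(mean_steps) <= 48.0

    def test_slow_steps_smaller_than_fast(self):
        """The operational definition of slowness: smaller trial-to-trial steps."""
        rng = np.random.default_rng(42)
        slow = np.mean([steps(generate_slow_sequence(GRID, 4, 30.0, rng)).mean() for _ in range(100)])
        fast = np.mean([steps(generate_fast_sequence(GRID, 4, rng)).mean() for _ in range(100)])
        assert slow < fast

    def test_rejects_too_few_positions(self, rng):
        with pytest.raises(ValueError):
            generate_slow_sequence(GRID[:1], 4, 30.0, rng)


class TestFastSequence:
    def test_no_smallest_or_zero_steps(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = steps(generate_fast_sequence(GRID, 4, rng))
            assert np.all(s > 24.0 + 1e-9)

    def test_balance(self, rng):
        seq = generate_fast_sequence(GRID, 4, rng)
        vals, counts = np.unique(seq, return_counts=True)
        assert len(vals) == 15 and np.all(counts == 4)

    def test_step_sizes_roughly_uniform_over_allowed_distances(self):
        """Eligible positions are drawn uniformly, so the six permitted
        step distances (48..168 degrees) occur at comparable rates."""
        rng = np.random.default_rng(9)
        all_steps = np.concatenate(
            [steps(generate_fast_sequence(GRID, 4, rng)) for _ in range(150)]
        )
        vals, counts = np.unique(all_steps, return_counts=True)
        assert set(vals) == {48.0, 72.0, 96.0, 120.0, 144.0, 168.0}
        freq = counts / counts.sum()
        assert freq.max() / freq.min() < 1.25


class TestSessionCounterbalancing:
    @pytest.mark.parametrize("seed", range(8))
    def test_invariants_hold_for_all_seeds(self, config, seed):
        sess = build_session(config, seed)
        specs = [b.spec for b in sess.blocks]
        conds = [s.condition for s in specs]
        assert conds.count("slow") == 4 and conds.count("fast") == 4
        # each (slow_dim x relevant_dim) cell once per half
        cells = [(s.slow_dim, s.relevant_dim) for s in specs]
        assert len(set(cells[:4])) == 4 and len(set(cells[4:])) == 4
        # distinct offsets, multiples of 3
        offsets = [s.grid_offset for s in specs]
        assert len(set(offsets)) == 8
        assert all(o % 3 == 0 for o in offsets)
        # each max-reward position once per relevant dimension
        for dim in ("shape", "colour"):
            used = sorted(s.max_reward_position for s in specs if s.relevant_dim == dim)
            assert used == [10.0, 100.0, 190.0, 280.0]
        for s in specs:
            assert np.allclose(
                sorted(circular_distance(s.test_positions, s.learning_positions)), 12.0
            )

    def test_phase_lengths(self, session):
        b = session.blocks[0]
        assert len(b.obs_slow) == 30
        assert len(b.learn_slow) == 60
        assert len(b.test_left) == 36

    def test_short_variant(self):
        cfg = SessionConfig.short_variant()
        sess = build_session(cfg, 0)
        b = sess.blocks[0]
        assert len(b.obs_slow) == 0
        assert len(b.learn_slow) == 45
        assert len(b.test_left) == 15

    def test_learning_rewards_match_relevant_angle(self, session):
        for b in session.blocks:
            rel = b.learn_slow if b.spec.condition == "slow" else b.learn_fast
            expected = [reward_of(a, b.spec.max_reward_position) for a in rel]
            assert np.allclose(b.learn_rewards, expected)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(n_positions=14)
        with pytest.raises(ValueError):
            SessionConfig(offset_step=12.0)  # only 2 distinct offsets


class TestTestPairs:
    def test_pair_construction(self, session, rng):
        for b in session.blocks:
            spec = b.spec
            left, right, rl, rr = generate_test_pairs(spec, 36, rng)
            rel_idx = 0 if spec.condition == "slow" else 1
            test_set = set(np.round(spec.test_positions, 6))
            for t in range(36):
                assert round(left[t, rel_idx], 6) in test_set
                assert round(right[t, rel_idx], 6) in test_set
                diff = abs(rl[t] - rr[t])
                assert 2.0 - 1e-9 <= diff <= 54.0 + 1e-9  # no identical-value pairs


class _Clairvoyant:
    """Oracle policy: accept exactly the stimuli worth more than 50 coins."""

    def start_block(self, spec):
        self.spec = spec

    def observe(self, s, f):
        pass

    def accept_prob(self, s, f, accept_key=0):
        rel = s if self.spec.condition == "slow" else f
        return 1.0 if reward_of(rel, self.spec.max_reward_position) > 50.0 else 0.0

    def update(self, s, f, choice, outcome):
        pass

    def test_values(self, left, right):
        idx = 0 if self.spec.condition == "slow" else 1
        return (
            reward_of(left[idx], self.spec.max_reward_position),
            reward_of(right[idx], self.spec.max_reward_position),
        )


class _AlwaysReject:
    def start_block(self, spec):
        pass

    def observe(self, s, f):
        pass

    def accept_prob(self, s, f, accept_key=0):
        return 0.0

    def update(self, *a):
        pass

    def test_values(self, left, right):
        return 0.0, 0.0


class TestEnvironment:
    def test_clairvoyant_gain_matches_oracle(self, session):
        log = run_environment(_Clairvoyant(), session, 0)
        for b in session.blocks:
            learn = log[(log["block"] == b.spec.block_index) & (log["phase"] == "learning")]
            gain = learn["outcome"].sum() - 50.0 * len(learn)
            assert gain == pytest.approx(clairvoyant_gain(b))

    def test_always_reject_gains_nothing(self, session):
        log = run_environment(_AlwaysReject(), session, 0)
        learn = log[log["phase"] == "learning"]
        assert learn["outcome"].sum() == pytest.approx(50.0 * len(learn))
        assert (learn["choice"] == "reject").all()

    def test_clairvoyant_perfect_at_test(self, session):
        log = run_environment(_Clairvoyant(), session, 0)
        assert log[log["phase"] == "test"]["correct"].all()

    def test_environment_reproducible(self, session, base_params):
        from slowrl.simulate import simulate_choices

        a = simulate_choices("1LR", base_params, session, 11)
        b = simulate_choices("1LR", base_params, session, 11)
        assert a.equals(b)

    def test_correctness_rule(self, session, base_params):
        from slowrl.simulate import simulate_choices

        log = simulate_choices("1LR", base_params, session, 11)
        learn = log[log["phase"] == "learning"]
        accept = learn["choice"] == "accept"
        high = learn["reward"] > 50.0
        assert (learn["correct"] == (accept == high)).all()
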