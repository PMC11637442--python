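"""Synthetic two-feature accept-reject bandit task.

Each session has eight blocks.  A stimulus is a pair of circular features
(shape angle, colour angle).  Within a block one dimension changes slowly
across trials (Gaussian random walk on the feature circle) and the other
quickly (random resampling with the smallest grid step forbidden); one
dimension — slow or fast — determines reward.  Blocks where the relevant
feature is the slow one are "slow blocks", otherwise "fast blocks".

A block runs through three phases: observation (passive exposure to feature
speed), learning (accept/reject choices with reward feedback), and test
(two-alternative choices between unseen feature values, no feedback).
Reward is a linear function of the circular distance between the relevant
feature angle and a hidden per-block maximum-reward position.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .circular import circular_distance, wrap_angle

__all__ = [
    "SessionConfig",
    "BlockSpec",
    "BlockTrials",
    "Session",
    "reward_of",
    "generate_slow_sequence",
    "generate_fast_sequence",
    "generate_test_pairs",
    "build_session",
    "run_environment",
    "clairvoyant_gain",
    "TRIAL_COLUMNS",
]

DIMENSIONS = ("shape", "colour")

#: column order of the trial-log interchange table
TRIAL_COLUMNS = [
    "participant",
    "block",
    "phase",
    "trial",
    "condition",
    "slow_deg",
    "fast_deg",
    "relevant_dim",
    "reward",
    "choice",
    "outcome",
    "correct",
    "accept_key",
    "slow_deg_right",
    "fast_deg_right",
    "reward_right",
]


class SessionConfig(BaseModel):
    """Design parameters of one task session.

    Defaults reproduce the full design: 8 counterbalanced blocks, a 15-position
    learning grid in 24-degree steps with per-block offsets in multiples of 3
    degrees, 30 observation / 60 learning / 36 test trials per block, a
    Gaussian random walk with SD 30 degrees for the slow feature, and
    maximum-reward positions at 10/100/190/280 degrees.  The shorter variant
    (no observation phase, 45 learning and 15 test trials, minimum test value
    difference 13 coins) is available through :meth:`short_variant`.
    """

    n_positions: int = 15
    grid_step: float = 24.0
    offset_step: float = 3.0
    observation_cycles: int = 2
    learning_cycles: int = 4
    n_test_trials: int = 36
    walk_sd: float = Field(30.0, gt=0)
    reward_positions: tuple[float, float, float, float] = (10.0, 100.0, 190.0, 280.0)
    test_offset: float = 12.0
    test_diff_min: float = 2.0
    test_diff_max: float = 54.0
    round_outcomes: bool = False

    @model_validator(mode="after")
    def _check_grid(self):
        if self.n_positions * self.grid_step != 360.0:
            raise ValueError("n_positions * grid_step must cover the circle exactly")
        n_offsets = int(self.grid_step // self.offset_step)
        if n_offsets < 8:
            raise ValueError(
                "need at least 8 distinct grid offsets for the 8 blocks "
                "(grid_step / offset_step >= 8)"
            )
        if len(set(self.reward_positions)) != 4:
            raise ValueError("reward_positions must be 4 distinct angles")
        return self

    @classmethod
    def short_variant(cls, **overrides) -> "SessionConfig":
        """The shorter design: no observation phase, 45/15 learning/test trials."""
        base = dict(
            observation_cycles=0,
            learning_cycles=3,
            n_test_trials=15,
            test_diff_min=13.0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def n_learning_trials(self) -> int:
        return self.n_positions * self.learning_cycles

    @property
    def n_observation_trials(self) -> int:
        return self.n_positions * self.observation_cycles


@dataclasses.dataclass(frozen=True)
class BlockSpec:
    """Full design of one task block."""

    block_index: int  # 1-based
    condition: str  # "slow" | "fast" (speed of the relevant feature)
    slow_dim: str  # "shape" | "colour"
    relevant_dim: str
    max_reward_position: float
    grid_offset: float
    learning_positions: np.ndarray
    test_positions: np.ndarray

    @property
    def fast_dim(self) -> str:
        return DIMENSIONS[1 - DIMENSIONS.index(self.slow_dim)]

    @property
    def slow_relevant(self) -> bool:
        return self.condition == "slow"


@dataclasses.dataclass
class BlockTrials:
    """Concrete trial sequences of one block (the stimulus/reward schedule)."""

    spec: BlockSpec
    obs_slow: np.ndarray
    obs_fast: np.ndarray
    learn_slow: np.ndarray
    learn_fast: np.ndarray
    learn_rewards: np.ndarray
    accept_key: np.ndarray  # 1 = right key means accept, per learning trial
    test_left: np.ndarray  # (n_test, 2): slow, fast angle of left stimulus
    test_right: np.ndarray
    test_reward_left: np.ndarray
    test_reward_right: np.ndarray

    def relevant_learning_angles(self) -> np.ndarray:
        return self.learn_slow if self.spec.slow_relevant else self.learn_fast


@dataclasses.dataclass
class Session:
    """One participant-session: eight blocks of scheduled trials."""

    participant: str
    config: SessionConfig
    blocks: list[BlockTrials]


def reward_of(relevant_angle, max_reward_position) -> float:
    """Reward (coins, 0-100) of a stimulus given its relevant feature angle.

    The circular distance to the maximum-reward position is subtracted from
    the largest possible distance (180 degrees) and rescaled to 0-100 coins:
    ``(180 - d) / 180 * 100``.
    """
    d = circular_distance(relevant_angle, max_reward_position)
    return (180.0 - d) / 180.0 * 100.0


def _nearest_unused(latent: float, positions: np.ndarray, used: np.ndarray) -> int:
    d = circular_distance(latent, positions)
    d = np.where(used, np.inf, d)
    return int(np.argmin(d))


def generate_slow_sequence(
    positions: Sequence[float],
    n_cycles: int,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow feature sequence: a Gaussian random walk snapped to the grid.

    The walk starts at a uniform-random angle; each subsequent trial proposes
    the previously shown angle plus a zero-mean Gaussian step with standard
    deviation ``sd`` degrees, and shows the grid position nearest the proposal
    among the positions not yet used in the current cycle — so every position
    appears exactly once per cycle of ``len(positions)`` trials while steps
    stay locally small.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least 2 grid positions")
    if sd <= 0:
        raise ValueError("walk sd must be positive")
    proposal = rng.uniform(0.0, 360.0)
    out = np.empty(n * n_cycles)
    t = 0
    for _ in range(n_cycles):
        used = np.zeros(n, dtype=bool)
        for _ in range(n):
            j = _nearest_unused(proposal, positions, used)
            used[j] = True
            out[t] = positions[j]
            proposal = (positions[j] + rng.normal(0.0, sd)) % 360.0
            t += 1
    return out


def generate_fast_sequence(
    positions: Sequence[float],
    n_cycles: int,
    rng: np.random.Generator,
    forbidden_step: float | None = None,
    max_retries: int = 1000,
) -> np.ndarray:
    """Fast feature sequence: random order with the smallest step forbidden.

    Each cycle shows every position exactly once in random order, with no two
    consecutive angles (including across cycle boundaries) separated by the
    smallest grid step (nor by zero).  Cycles that paint themselves into a
    corner are resampled.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        raise ValueError("need at least 2 grid positions")
    if forbidden_step is None:
        diffs = circular_distance(positions[:, None], positions[None, :])
        forbidden_step = float(np.min(diffs[diffs > 1e-9]))
    out = np.empty(n * n_cycles)
    prev = None
    t = 0
    for _ in range(n_cycles):
        for attempt in range(max_retries):
            seq = _sample_cycle(positions, prev, forbidden_step, rng)
            if seq is not None:
                break
        else:
            raise RuntimeError("could not satisfy fast-sequence step constraint")
        out[t : t + n] = seq
        prev = seq[-1]
        t += n
    return out


def _sample_cycle(positions, prev, forbidden_step, rng):
    n = len(positions)
    used = np.zeros(n, dtype=bool)
    seq = np.empty(n)
    for i in range(n):
        if prev is None:
            eligible = ~used
        else:
            d = circular_distance(prev, positions)
            eligible = (~used) & (d > forbidden_step + 1e-9)
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            return None
        j = int(rng.choice(idx))
        used[j] = True
        seq[i] = positions[j]
        prev = positions[j]
    return seq


def generate_test_pairs(
    block: BlockSpec,
    n_trials: int,
    rng: np.random.Generator,
    diff_min: float = 2.0,
    diff_max: float = 54.0,
    n_bins: int = 6,
):
    """Draw test-phase stimulus pairs with controlled value differences.

    Both stimuli's relevant feature angles come from the block's test grid
    (offset 12 degrees from the learning grid); irrelevant angles are sampled
    uniformly from the same grid.  The absolute difference in value between
    the two stimuli is stratified into ``n_bins`` uniform bins spanning
    ``[diff_min, diff_max]`` coins; pairs of identical value are excluded by
    construction.  Returns left/right stimulus angle arrays (slow, fast) and
    the relevant-feature values of each side.
    """
    pos = np.asarray(block.test_positions, dtype=float)
    values = np.array([reward_of(p, block.max_reward_position) for p in pos])
    ii, jj = np.triu_indices(len(pos), k=1)
    diffs = np.abs(values[ii] - values[jj])
    keep = (diffs >= diff_min) & (diffs <= diff_max)
    ii, jj, diffs = ii[keep], jj[keep], diffs[keep]
    if ii.size == 0:
        raise ValueError("no test pairs available in the requested difference range")
    edges = np.linspace(diff_min, diff_max, n_bins + 1)
    bins = [np.flatnonzero((diffs >= lo) & (diffs <= hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    bins = [b for b in bins if b.size > 0]
    left = np.empty((n_trials, 2))
    right = np.empty((n_trials, 2))
    rew_l = np.empty(n_trials)
    rew_r = np.empty(n_trials)
    slow_rel = block.slow_relevant
    for t in range(n_trials):
        b = bins[t % len(bins)]
        k = int(rng.choice(b))
        a_rel, b_rel = pos[ii[k]], pos[jj[k]]
        if rng.random() < 0.5:  # randomise left/right assignment
            a_rel, b_rel = b_rel, a_rel
        a_irr = float(rng.choice(pos))
        b_irr = float(rng.choice(pos))
        if slow_rel:
            left[t] = (a_rel, a_irr)
            right[t] = (b_rel, b_irr)
        else:
            left[t] = (a_irr, a_rel)
            right[t] = (b_irr, b_rel)
        rew_l[t] = reward_of(a_rel, block.max_reward_position)
        rew_r[t] = reward_of(b_rel, block.max_reward_position)
    return left, right, rew_l, rew_r


def _block_order(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Pseudo-random order of (slow_dim, relevant_dim) cells: each of the four
    cells appears once in the first four blocks and once in the last four."""
    cells = [(s, r) for s in DIMENSIONS for r in DIMENSIONS]
    first = [cells[i] for i in rng.permutation(4)]
    second = [cells[i] for i in rng.permutation(4)]
    return first + second


def build_session(
    config: SessionConfig,
    seed,
    participant: str = "sim",
) -> Session:
    """Generate a full counterbalanced session (the stimulus/reward schedule).

    Counterbalancing: each (feature-speed x relevant-dimension) cell occurs
    twice, once in each half of the session; every block uses a distinct grid
    offset; each maximum-reward position is used once per relevant dimension.
    Observation and learning sequences are sampled independently.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = _block_order(rng)
    n_offsets = int(config.grid_step // config.offset_step)
    offsets = rng.permutation(n_offsets)[:8] * config.offset_step
    # one random assignment of the four reward positions per relevant dimension
    rewpos = {
        dim: list(np.array(config.reward_positions)[rng.permutation(4)])
        for dim in DIMENSIONS
    }
    blocks = []
    for b, (slow_dim, relevant_dim) in enumerate(order, start=1):
        offset = float(offsets[b - 1])
        learning_positions = wrap_angle(offset + config.grid_step * np.arange(config.n_positions))
        test_positions = wrap_angle(learning_positions + config.test_offset)
        spec = BlockSpec(
            block_index=b,
            condition="slow" if slow_dim == relevant_dim else "fast",
            slow_dim=slow_dim,
            relevant_dim=relevant_dim,
            max_reward_position=float(rewpos[relevant_dim].pop()),
            grid_offset=offset,
            learning_positions=learning_positions,
            test_positions=test_positions,
        )
        blocks.append(_build_block_trials(spec, config, rng))
    return Session(participant=participant, config=config, blocks=blocks)


def _build_block_trials(spec: BlockSpec, config: SessionConfig, rng) -> BlockTrials:
    pos = spec.learning_positions
    if config.observation_cycles > 0:
        obs_slow = generate_slow_sequence(pos, config.observation_cycles, config.walk_sd, rng)
        obs_fast = generate_fast_sequence(pos, config.observation_cycles, rng)
    else:
        obs_slow = np.empty(0)
        obs_fast = np.empty(0)
    learn_slow = generate_slow_sequence(pos, config.learning_cycles, config.walk_sd, rng)
    learn_fast = generate_fast_sequence(pos, config.learning_cycles, rng)
    relevant = learn_slow if spec.slow_relevant else learn_fast
    rewards = np.array([reward_of(a, spec.max_reward_position) for a in relevant])
    accept_key = rng.integers(0, 2, size=len(relevant))
    left, right, rew_l, rew_r = generate_test_pairs(
        spec,
        config.n_test_trials,
        rng,
        diff_min=config.test_diff_min,
        diff_max=config.test_diff_max,
    )
    return BlockTrials(
        spec=spec,
        obs_slow=obs_slow,
        obs_fast=obs_fast,
        learn_slow=learn_slow,
        learn_fast=learn_fast,
        learn_rewards=rewards,
        accept_key=accept_key,
        test_left=left,
        test_right=right,
        test_reward_left=rew_l,
        test_reward_right=rew_r,
    )


def clairvoyant_gain(block: BlockTrials) -> float:
    """Upper bound on cumulative reward gain: accept exactly the stimuli worth
    more than the 50-coin reject value."""
    return float(np.sum(np.maximum(block.learn_rewards - 50.0, 0.0)))


def run_environment(agent, session: Session, seed) -> pd.DataFrame:
    """Run an agent through a session and return the trial log.

    Learning phase: the agent's accept probability is sampled; accepting
    yields the stimulus reward, rejecting the fixed 50 coins; a choice is
    correct iff it accepts a stimulus worth more than 50 (rejects one worth
    less).  Test phase: the agent's stimulus values are compared and the
    higher-valued side chosen (ties uniform at random); no feedback reaches
    the agent.  Observation trials are passed to ``agent.observe``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows: list[dict] = []
    for block in session.blocks:
        spec = block.spec
        agent.start_block(spec)
        base = dict(
            participant=session.participant,
            block=spec.block_index,
            condition=spec.condition,
            relevant_dim=spec.relevant_dim,
        )
        for t in range(len(block.obs_slow)):
            s, f = block.obs_slow[t], block.obs_fast[t]
            agent.observe(s, f)
            rel = s if spec.slow_relevant else f
            rows.append(
                dict(
                    base,
                    phase="observation",
                    trial=t + 1,
                    slow_deg=s,
                    fast_deg=f,
                    reward=reward_of(rel, spec.max_reward_position),
                    choice="none",
                    outcome=np.nan,
                    correct=np.nan,
                    accept_key=np.nan,
                    slow_deg_right=np.nan,
                    fast_deg_right=np.nan,
                    reward_right=np.nan,
                )
            )
        for t in range(len(block.learn_slow)):
            s, f = block.learn_slow[t], block.learn_fast[t]
            r = block.learn_rewards[t]
            key = int(block.accept_key[t])
            p = agent.accept_prob(s, f, accept_key=key)
            accept = rng.random() < p
            outcome = r if accept else 50.0
            if session.config.round_outcomes:
                outcome = float(np.round(outcome))
            agent.update(s, f, "accept" if accept else "reject", outcome)
            rows.append(
                dict(
                    base,
                    phase="learning",
                    trial=t + 1,
                    slow_deg=s,
                    fast_deg=f,
                    reward=r,
                    choice="accept" if accept else "reject",
                    outcome=outcome,
                    correct=bool(accept == (r > 50.0)),
                    accept_key=key,
                    slow_deg_right=np.nan,
                    fast_deg_right=np.nan,
                    reward_right=np.nan,
                )
            )
        for t in range(len(block.test_left)):
            (ls, lf), (rs, rf) = block.test_left[t], block.test_right[t]
            v_l, v_r = agent.test_values((ls, lf), (rs, rf))
            u = rng.random()  # consumed every trial to keep draw streams aligned
            if v_l > v_r:
                choice = "left"
            elif v_r > v_l:
                choice = "right"
            else:
                choice = "left" if u < 0.5 else "right"
            rl, rr = block.test_reward_left[t], block.test_reward_right[t]
            chosen = rl if choice == "left" else rr
            rows.append(
                dict(
                    base,
                    phase="test",
                    trial=t + 1,
                    slow_deg=ls,
                    fast_deg=lf,
                    reward=rl,
                    choice=choice,
                    outcome=np.nan,
                    correct=bool(chosen == max(rl, rr)),
                    accept_key=np.nan,
                    slow_deg_right=rs,
                    fast_deg_right=rf,
                    reward_right=rr,
                )
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
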