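"""Forward simulation of models through task sessions.

``simulate_choices`` produces a full trial log (observation, learning and
test rows) using the reference agent classes.  ``simulate_gains`` is the lean
fast path used by parameter search and large simulation studies: it returns
only per-block cumulative reward gains and test accuracies, running the
learning models through the compiled kernels.  Both paths consume the random
stream in the same per-trial order, so a given seed yields the same choices.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kernels
from .agents import MODELS, make_agent, resolve_block_params
from .circular import DEFAULT_NODE_COUNT, basis_matrix
from .task import Session, run_environment

__all__ = ["simulate_choices", "simulate_gains", "gains_from_log"]


def simulate_choices(
    model_id: str,
    params: Mapping[str, float],
    session: Session,
    seed,
    node_count: int = DEFAULT_NODE_COUNT,
) -> pd.DataFrame:
    """Simulate a model through one session and return its trial log.

    Learning-phase choices are drawn from the model's accept probability;
    test-phase choices pick the stimulus with the higher model value (ties
    uniform at random, so feature-blind models sit at 50% accuracy).
    """
    agent = make_agent(model_id, params, node_count)
    return run_environment(agent, session, seed)


def gains_from_log(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Per-block cumulative reward gain and test accuracy from a trial log.

    Gain is the summed outcome of responded learning trials minus the 50-coin
    chance baseline per trial.
    """
    rows = []
    for (participant, block), grp in trial_log.groupby(["participant", "block"], sort=True):
        learn = grp[(grp["phase"] == "learning") & (grp["choice"] != "none")]
        test = grp[grp["phase"] == "test"]
        rows.append(
            dict(
                participant=participant,
                block=block,
                condition=grp["condition"].iloc[0],
                gain=float(learn["outcome"].sum() - 50.0 * len(learn)),
                learn_accuracy=float(learn["correct"].mean()) if len(learn) else np.nan,
                test_accuracy=float(test["correct"].mean()) if len(test) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def simulate_gains(
    model_id: str,
    params: Mapping[str, float],
    sessions: Sequence[Session],
    seed: int,
    node_count: int = DEFAULT_NODE_COUNT,
) -> pd.DataFrame:
    """Per-block gains and test accuracy for a model over several sessions.

    Session ``i`` uses the deterministic stream seeded ``seed + i``, so a
    fixed ``seed`` gives common random numbers across calls — useful when an
    optimiser compares parameter settings on a stochastic objective.
    """
    spec = MODELS[model_id]
    if spec.kind == "fa":
        return _fa_gains(model_id, params, sessions, seed, node_count)
    rows = []
    for i, session in enumerate(sessions):
        log = simulate_choices(model_id, params, session, seed + i, node_count)
        g = gains_from_log(log)
        g.insert(0, "session", i)
        rows.append(g)
    return pd.concat(rows, ignore_index=True)


def _fa_gains(model_id, params, sessions, seed, node_count):
    kappa = params["kappa"]
    rows = []
    for i, session in enumerate(sessions):
        rng = np.random.default_rng(seed + i)
        for block in session.blocks:
            spec = block.spec
            bp = resolve_block_params(model_id, params, spec)
            x_s = basis_matrix(block.learn_slow, kappa, node_count)
            x_f = basis_matrix(block.learn_fast, kappa, node_count)
            rewards = block.learn_rewards
            n_learn = len(rewards)
            choices = np.zeros(n_learn, dtype=np.int64)
            u_learn = rng.random(n_learn)
            p = np.empty(n_learn)
            w, v = kernels.fa_state_init(node_count)
            kernels.fa_block(
                x_s, x_f, rewards, choices, u_learn,
                bp.c, bp.sigma, bp.alpha_s0, bp.alpha_f0, bp.m_s, bp.m_f,
                bp.mean_update, True, p, w, v,
            )
            outcomes = np.where(choices == 1, rewards, 50.0)
            gain = float(outcomes.sum() - 50.0 * n_learn)
            learn_acc = float(np.mean((choices == 1) == (rewards > 50.0)))
            # test phase: compare final-state values of the two stimuli
            n_test = len(block.test_left)
            u_test = rng.random(n_test)
            v_l = np.empty(n_test)
            v_r = np.empty(n_test)
            kernels.fa_values(
                basis_matrix(block.test_left[:, 0], kappa, node_count),
                basis_matrix(block.test_left[:, 1], kappa, node_count),
                w, v_l,
            )
            kernels.fa_values(
                basis_matrix(block.test_right[:, 0], kappa, node_count),
                basis_matrix(block.test_right[:, 1], kappa, node_count),
                w, v_r,
            )
            pick_left = np.where(v_l == v_r, u_test < 0.5, v_l > v_r)
            chosen = np.where(pick_left, block.test_reward_left, block.test_reward_right)
            best = np.maximum(block.test_reward_left, block.test_reward_right)
            rows.append(
                dict(
                    session=i,
                    participant=session.participant,
                    block=spec.block_index,
                    condition=spec.condition,
                    gain=gain,
                    learn_accuracy=learn_acc,
                    test_accuracy=float(np.mean(chosen == best)),
                )
            )
    return pd.DataFrame(rows)
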