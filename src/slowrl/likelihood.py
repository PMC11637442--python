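"""Choice likelihoods of all models on trial logs.

The negative log likelihood is computed over responded learning-phase trials
only (observation trials carry no choice; test trials are never fitted), with
model state reset at the start of every block.  Per-trial probabilities are
floored at 1e-12 so the NLL stays finite everywhere in the parameter box.
"""

from __future__ import annotations

import types
from typing import Mapping

import numpy as np
import pandas as pd

from . import kernels
from .agents import MODELS, make_agent, measurement_noise, resolve_block_params
from .circular import DEFAULT_NODE_COUNT, basis_cosines

__all__ = ["nll_choices", "nll_choices_reference", "learning_blocks", "extract_blocks"]

_P_FLOOR = 1e-12


class ExtractedBlocks(list):
    """Pre-extracted per-block arrays of one participant's learning trials.

    Avoids re-parsing the trial-log DataFrame (and recomputing basis cosine
    tables) on every likelihood evaluation inside an optimiser loop;
    ``nll_choices`` accepts this in place of the DataFrame.
    """

    node_count: int = DEFAULT_NODE_COUNT


def extract_blocks(trial_log: pd.DataFrame, node_count: int = DEFAULT_NODE_COUNT) -> ExtractedBlocks:
    out = ExtractedBlocks(learning_blocks(trial_log))
    out.node_count = node_count
    # kappa-independent cosine tables, exponentiated per likelihood call
    out.cosines = [
        (basis_cosines(s, node_count), basis_cosines(f, node_count))
        for _, s, f, _, _, _ in out
    ]
    return out


def learning_blocks(trial_log: pd.DataFrame):
    """Yield per-block arrays of responded learning trials, in block order.

    Yields ``(condition, slow_deg, fast_deg, rewards, choices, accept_key)``
    with choices coded 1 = accept, 0 = reject; no-response trials are dropped
    (they contribute no likelihood and cause no model update).
    """
    if isinstance(trial_log, ExtractedBlocks):
        yield from trial_log
        return
    learn = trial_log[trial_log["phase"] == "learning"]
    learn = learn[learn["choice"].isin(["accept", "reject"])]
    if learn["participant"].nunique() > 1:
        raise ValueError("trial log contains several participants; fit them separately")
    for block_id, grp in learn.groupby("block", sort=True):
        grp = grp.sort_values("trial")
        cond = grp["condition"].iloc[0]
        key = grp["accept_key"].to_numpy(dtype=float)
        key = np.where(np.isnan(key), 0, key).astype(np.int64)
        yield (
            str(cond),
            grp["slow_deg"].to_numpy(dtype=float),
            grp["fast_deg"].to_numpy(dtype=float),
            grp["reward"].to_numpy(dtype=float),
            (grp["choice"] == "accept").to_numpy(dtype=np.int64),
            key,
        )


def _choice_nll(p_accept: np.ndarray, choices: np.ndarray) -> float:
    p = np.clip(p_accept, _P_FLOOR, 1.0 - _P_FLOOR)
    ll = np.where(choices == 1, np.log(p), np.log1p(-p))
    return float(-np.sum(ll))


def _exp_normalise(cosd: np.ndarray, kappa: float) -> np.ndarray:
    a = kappa * cosd
    x = np.exp(a - a.max(axis=1, keepdims=True))
    x /= x.sum(axis=1, keepdims=True)
    return x


def nll_choices(
    model_id: str,
    params: Mapping[str, float],
    trial_log,
    node_count: int = DEFAULT_NODE_COUNT,
) -> float:
    """Negative log likelihood of one participant's learning-phase choices.

    Deterministic given its inputs.  Function-approximation models and the
    bandit run through the compiled kernels; the heuristic controls have
    closed-form per-trial probabilities.  ``trial_log`` may be the DataFrame
    or the output of :func:`extract_blocks` (much faster when called
    repeatedly, e.g. inside an optimiser).
    """
    spec = MODELS[model_id]
    total = 0.0
    dummy_u = np.empty(0)
    if spec.kind == "fa":
        if isinstance(trial_log, ExtractedBlocks):
            if trial_log.node_count != node_count:
                raise ValueError("extract_blocks node_count does not match")
            data = trial_log
            cos_tables = data.cosines
        else:
            data = extract_blocks(trial_log, node_count)
            cos_tables = data.cosines
        kappa = params["kappa"]
        for (cond, _, _, rewards, choices, _), (cos_s, cos_f) in zip(data, cos_tables):
            x_s = _exp_normalise(cos_s, kappa)
            x_f = _exp_normalise(cos_f, kappa)
            bp = resolve_block_params(model_id, params, types.SimpleNamespace(condition=cond))
            w, v = kernels.fa_state_init(node_count)
            p = np.empty(len(rewards))
            kernels.fa_block(
                x_s, x_f, rewards, choices, dummy_u,
                bp.c, bp.sigma, bp.alpha_s0, bp.alpha_f0, bp.m_s, bp.m_f,
                bp.mean_update, False, p, w, v,
            )
            total += _choice_nll(p, choices)
        return total
    if spec.kind == "bandit":
        m = measurement_noise(params["alpha"])
        for _, _, _, rewards, choices, _ in learning_blocks(trial_log):
            p = np.empty(len(rewards))
            kernels.bandit_block(
                rewards, choices, dummy_u, params["c"], params["sigma"],
                params["alpha"], m, False, p,
            )
            total += _choice_nll(p, choices)
        return total
    if spec.kind == "wsls":
        eps = params["epsilon"]
        for _, _, _, rewards, choices, _ in learning_blocks(trial_log):
            outcomes = np.where(choices == 1, rewards, 50.0)
            p = np.full(len(choices), 0.5)
            if len(choices) > 1:
                win = (choices[:-1] == 1) & (outcomes[:-1] >= 50.0)
                p[1:] = np.where(win, 1.0 - eps, eps)
            total += _choice_nll(p, choices)
        return total
    if spec.kind == "random_choice":
        for _, _, _, _, choices, _ in learning_blocks(trial_log):
            p = np.full(len(choices), params["b_a"])
            total += _choice_nll(p, choices)
        return total
    if spec.kind == "random_key":
        for _, _, _, _, choices, key in learning_blocks(trial_log):
            p = np.where(key == 1, params["b_r"], 1.0 - params["b_r"])
            total += _choice_nll(p, choices)
        return total
    raise KeyError(model_id)


def nll_choices_reference(
    model_id: str,
    params: Mapping[str, float],
    trial_log: pd.DataFrame,
    node_count: int = DEFAULT_NODE_COUNT,
) -> float:
    """Step-by-step NLL via the reference agent classes (slow, general path)."""
    total = 0.0
    for cond, s, f, rewards, choices, key in learning_blocks(trial_log):
        agent = make_agent(model_id, params, node_count)
        agent.start_block(types.SimpleNamespace(condition=cond))
        for t in range(len(rewards)):
            p = agent.accept_prob(s[t], f[t], accept_key=int(key[t]))
            p = min(max(p, _P_FLOOR), 1.0 - _P_FLOOR)
            accept = choices[t] == 1
            total -= np.log(p) if accept else np.log1p(-p)
            outcome = rewards[t] if accept else 50.0
            agent.update(s[t], f[t], "accept" if accept else "reject", outcome)
    return total
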