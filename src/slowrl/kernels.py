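"""Compiled inner loops for likelihood evaluation and simulation.

These kernels are numerically equivalent to the step-by-step reference
classes in :mod:`slowrl.agents` (asserted by the test suite) but run the
whole learning phase of a block in one call.  They take pre-computed basis
matrices (one row per trial, one column per node of one feature dimension),
so the caller controls the encoding; recomputing the bases for a new
concentration is a vectorised exponential over a kappa-independent cosine
table and costs little.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_P_FLOOR = 1e-12
_REJECT = 50.0
_U_INIT = 5.0
_W_INIT = 25.0


@njit(cache=True)
def _phi(z):
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@njit(cache=True)
def _clip_p(p):
    if p < _P_FLOOR:
        return _P_FLOOR
    if p > 1.0 - _P_FLOOR:
        return 1.0 - _P_FLOOR
    return p


@njit(cache=True)
def _rate(u, m):
    if math.isinf(m):
        return 0.0
    denom = u + m
    if denom <= 0.0:
        return 0.0
    return u / denom


@njit(cache=True, fastmath=True)
def fa_block(
    x_s,
    x_f,
    rewards,
    choices,
    u_draws,
    c,
    sigma,
    alpha_s,
    alpha_f,
    m_s,
    m_f,
    mean_update,
    simulate,
    p_out,
    w,
    v,
):
    """Run the function-approximation learner through one block's learning phase.

    ``x_s``/``x_f`` are (n_trials, n_nodes) basis matrices of the slow/fast
    feature.  In simulation mode choices are drawn (``u < p``) and written
    into ``choices``; otherwise observed choices (1 accept, 0 reject) are
    read.  ``w`` and ``v`` are the (2, n_nodes) weight/variance state,
    initialised by the caller and mutated in place; ``p_out`` receives
    per-trial accept probabilities.
    """
    n = x_s.shape[1]
    w_s = w[0]
    w_f = w[1]
    v_s = v[0]
    v_f = v[1]
    for t in range(x_s.shape[0]):
        vs = 0.0
        us = 0.0
        vf = 0.0
        uf = 0.0
        for j in range(n):
            vs += x_s[t, j] * w_s[j]
            us += x_s[t, j] * v_s[j]
            vf += x_f[t, j] * w_f[j]
            uf += x_f[t, j] * v_f[j]
        value = vs + vf
        va = value + c * (us + uf)
        p = _clip_p(_phi((va - _REJECT) / sigma))
        p_out[t] = p
        if simulate:
            ch = 1 if u_draws[t] < p else 0
            choices[t] = ch
        else:
            ch = choices[t]
        if ch == 1:
            delta = rewards[t] - value
            for j in range(n):
                w_s[j] += alpha_s * x_s[t, j] * delta
                v_s[j] -= alpha_s * x_s[t, j] * v_s[j]
                if v_s[j] < 0.0:
                    v_s[j] = 0.0
                w_f[j] += alpha_f * x_f[t, j] * delta
                v_f[j] -= alpha_f * x_f[t, j] * v_f[j]
                if v_f[j] < 0.0:
                    v_f[j] = 0.0
            if mean_update:
                alpha_s = _rate(0.5 * (us + uf), m_s)
                alpha_f = alpha_s
            else:
                alpha_s = _rate(us, m_s)
                alpha_f = _rate(uf, m_f)


@njit(cache=True, fastmath=True)
def fa_values(x_s, x_f, w, out):
    """Stimulus values ``V = x.w`` for rows of (slow, fast) basis matrices."""
    n = x_s.shape[1]
    w_s = w[0]
    w_f = w[1]
    for t in range(x_s.shape[0]):
        total = 0.0
        for j in range(n):
            total += x_s[t, j] * w_s[j] + x_f[t, j] * w_f[j]
        out[t] = total


@njit(cache=True)
def bandit_block(rewards, choices, u_draws, c, sigma, alpha0, m, simulate, p_out):
    """Scalar Kalman-filter control model over one block's learning phase."""
    value = _REJECT
    unc = _U_INIT
    alpha = alpha0
    for t in range(rewards.shape[0]):
        va = value + c * unc
        p = _clip_p(_phi((va - _REJECT) / sigma))
        p_out[t] = p
        if simulate:
            ch = 1 if u_draws[t] < p else 0
            choices[t] = ch
        else:
            ch = choices[t]
        if ch == 1:
            u_pre = unc
            value += alpha * (rewards[t] - value)
            unc -= alpha * unc
            alpha = _rate(u_pre, m)


def fa_state_init(node_count: int) -> tuple[np.ndarray, np.ndarray]:
    """Block-start weights and variances: V = 50 and U = 5 per feature for any
    stimulus (weights 25 per node, variances 5 per node, bases summing to 1)."""
    w = np.full((2, node_count), _W_INIT)
    v = np.full((2, node_count), _U_INIT)
    return w, v
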