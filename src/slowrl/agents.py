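"""Behavioural models of the accept-reject task.

Four learning models share one mechanism — linear function approximation
over von Mises feature bases combined with a Kalman filter — and differ only
in how many learning rates they carry and which feature/block combination
each rate applies to:

* ``1LR`` — one rate for everything.
* ``2LRf`` — one rate per feature speed (slow vs fast feature), in every block.
* ``2LRc`` — one rate per block condition (slow vs fast block), shared by
  both features within the block.
* ``4LR`` — one rate per (feature speed x relevance) combination.

Two variants let a non-learning parameter vary with block condition instead
(``1LRc``: exploration weight; ``1LRsigma2``: decision noise), and four
control models test simpler strategies: a feature-blind scalar Kalman filter
(``bandit``), win-stay/lose-shift (``wsls``), and biased random responding by
choice (``random_choice``) or by response key (``random_key``).

The classes here are the readable reference implementation, stepped one trial
at a time; :mod:`slowrl.kernels` holds the numerically identical compiled
fast path used by fitting and large simulations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np

from .circular import DEFAULT_NODE_COUNT, encode_feature

__all__ = [
    "MODEL_IDS",
    "LEARNING_MODELS",
    "MODELS",
    "ModelSpec",
    "BlockParams",
    "resolve_block_params",
    "measurement_noise",
    "p_accept",
    "stimulus_value",
    "accept_value",
    "make_agent",
    "KalmanFALearner",
    "BanditAgent",
    "WSLSAgent",
    "RandomChoiceAgent",
    "RandomKeyAgent",
]

#: reject value / reward expected by chance, in coins
REJECT_VALUE = 50.0
#: per-feature uncertainty bonus at block start
U_INIT = 5.0
#: per-trial likelihood floor keeping log-probabilities finite
P_FLOOR = 1e-12

_SQRT2 = math.sqrt(2.0)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Registry entry: free parameters (in fitting order) and their box bounds."""

    model_id: str
    kind: str  # "fa" | "bandit" | "wsls" | "random_choice" | "random_key"
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    @property
    def k(self) -> int:
        """Number of free parameters (the AICc ``k``)."""
        return len(self.param_names)


_ALPHA = (0.0, 1.0)
_KAPPA = (0.0, 30.0)
_C = (0.0, 20.0)
_SIGMA = (1.0, 150.0)
_PROB = (0.001, 0.999)

MODELS: dict[str, ModelSpec] = {
    s.model_id: s
    for s in [
        ModelSpec("1LR", "fa", ("kappa", "c", "sigma", "alpha"), (_KAPPA, _C, _SIGMA, _ALPHA)),
        ModelSpec(
            "2LRf", "fa", ("kappa", "c", "sigma", "alpha_S", "alpha_F"),
            (_KAPPA, _C, _SIGMA, _ALPHA, _ALPHA),
        ),
        ModelSpec(
            "2LRc", "fa", ("kappa", "c", "sigma", "alpha_S", "alpha_F"),
            (_KAPPA, _C, _SIGMA, _ALPHA, _ALPHA),
        ),
        ModelSpec(
            "4LR", "fa",
            ("kappa", "c", "sigma", "alpha_SR", "alpha_FR", "alpha_SI", "alpha_FI"),
            (_KAPPA, _C, _SIGMA, _ALPHA, _ALPHA, _ALPHA, _ALPHA),
        ),
        ModelSpec(
            "1LRc", "fa", ("kappa", "c_slow", "c_fast", "sigma", "alpha"),
            (_KAPPA, _C, _C, _SIGMA, _ALPHA),
        ),
        ModelSpec(
            "1LRsigma2", "fa", ("kappa", "c", "sigma_slow", "sigma_fast", "alpha"),
            (_KAPPA, _C, _SIGMA, _SIGMA, _ALPHA),
        ),
        ModelSpec("bandit", "bandit", ("c", "sigma", "alpha"), (_C, _SIGMA, _ALPHA)),
        ModelSpec("wsls", "wsls", ("epsilon",), (_PROB,)),
        ModelSpec("random_choice", "random_choice", ("b_a",), (_PROB,)),
        ModelSpec("random_key", "random_key", ("b_r",), (_PROB,)),
    ]
}

MODEL_IDS = tuple(MODELS)
LEARNING_MODELS = ("1LR", "2LRf", "2LRc", "4LR")


def measurement_noise(alpha0: float, u0: float = U_INIT) -> float:
    """Constant measurement noise implied by a first-trial learning rate.

    Inverts the Kalman learning-rate recursion ``alpha = U / (U + M)`` at the
    initial uncertainty ``u0`` so the rate on the first trial of every block
    equals the fitted ``alpha0``.  ``alpha0 = 0`` maps to infinite noise (no
    learning); ``alpha0 = 1`` to zero noise (full steps).
    """
    if not 0.0 <= alpha0 <= 1.0:
        raise ValueError("learning rate must lie in [0, 1]")
    if alpha0 <= 0.0:
        return math.inf
    return u0 * (1.0 - alpha0) / alpha0


def p_accept(va: float, sigma: float) -> float:
    """Probability of accepting: P[X <= V_a] for X ~ Normal(50, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    p = 0.5 * (1.0 + math.erf((va - REJECT_VALUE) / (sigma * _SQRT2)))
    return min(max(p, P_FLOOR), 1.0 - P_FLOOR)


def stimulus_value(weights: np.ndarray, basis: np.ndarray) -> float:
    """Expected value of a stimulus: inner product of basis and weights.

    Both arrays are the concatenation of the slow and fast feature blocks
    (or any matching layout); a dimension mismatch raises.
    """
    weights = np.asarray(weights, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if weights.shape != basis.shape:
        raise ValueError("basis and weight layouts do not match")
    return float(basis.ravel() @ weights.ravel())


def accept_value(value: float, uncertainty: float, c: float) -> float:
    """Value of accepting: stimulus value plus the weighted exploration bonus."""
    return value + c * uncertainty


@dataclasses.dataclass(frozen=True)
class BlockParams:
    """Per-block resolution of a model's parameters onto the two features.

    ``alpha_s0``/``alpha_f0`` are the first-trial learning rates applied to the
    slow and fast feature dimension in this block; ``m_s``/``m_f`` the matching
    measurement-noise constants.  When ``mean_update`` is set the two rates are
    tied and updated from the mean of the two per-feature uncertainties.
    """

    c: float
    sigma: float
    alpha_s0: float
    alpha_f0: float
    m_s: float
    m_f: float
    mean_update: bool


def resolve_block_params(model_id: str, params: Mapping[str, float], spec) -> BlockParams:
    """Map a model's fitted parameters onto one block's learning-rate slots.

    ``spec`` must expose ``condition`` ("slow"/"fast"): the learning-rate
    structure is allowed to know from trial 1 which feature is slow and which
    is relevant.
    """
    slow_block = spec.condition == "slow"
    c = params.get("c", 0.0)
    sigma = params.get("sigma", 1.0)
    if model_id == "1LR":
        a = params["alpha"]
        return BlockParams(c, sigma, a, a, measurement_noise(a), measurement_noise(a), True)
    if model_id == "2LRf":
        a_s, a_f = params["alpha_S"], params["alpha_F"]
        return BlockParams(
            c, sigma, a_s, a_f, measurement_noise(a_s), measurement_noise(a_f), False
        )
    if model_id == "2LRc":
        a = params["alpha_S"] if slow_block else params["alpha_F"]
        return BlockParams(c, sigma, a, a, measurement_noise(a), measurement_noise(a), True)
    if model_id == "4LR":
        a_s = params["alpha_SR"] if slow_block else params["alpha_SI"]
        a_f = params["alpha_FI"] if slow_block else params["alpha_FR"]
        return BlockParams(
            c, sigma, a_s, a_f, measurement_noise(a_s), measurement_noise(a_f), False
        )
    if model_id == "1LRc":
        a = params["alpha"]
        c = params["c_slow"] if slow_block else params["c_fast"]
        return BlockParams(c, sigma, a, a, measurement_noise(a), measurement_noise(a), True)
    if model_id == "1LRsigma2":
        a = params["alpha"]
        sigma = params["sigma_slow"] if slow_block else params["sigma_fast"]
        return BlockParams(c, sigma, a, a, measurement_noise(a), measurement_noise(a), True)
    raise KeyError(f"unknown learning-rate structure: {model_id}")


def _next_rate(u: float, m: float) -> float:
    """Kalman learning-rate recursion with guards at the closed ends."""
    if math.isinf(m):
        return 0.0
    denom = u + m
    if denom <= 0.0:
        return 0.0
    return u / denom


class _Agent:
    """Minimal agent protocol used by the simulation environment."""

    def start_block(self, spec) -> None:  # pragma: no cover - trivial default
        pass

    def observe(self, slow_deg: float, fast_deg: float) -> None:
        pass

    def accept_prob(self, slow_deg: float, fast_deg: float, accept_key: int = 0) -> float:
        raise NotImplementedError

    def update(self, slow_deg: float, fast_deg: float, choice: str, outcome: float) -> None:
        pass

    def test_values(self, left: tuple, right: tuple) -> tuple[float, float]:
        """Values of the two test stimuli; equal values mean a random guess."""
        return 0.0, 0.0


class KalmanFALearner(_Agent):
    """Kalman-filter learner with linear function approximation.

    Keeps one weight (value) and one variance (uncertainty) per basis node
    for each feature dimension.  At choice the stimulus value ``V = x.w`` is
    augmented by ``c`` times the summed per-feature uncertainty ``U = x.v``;
    the accept probability is the normal CDF of ``V_a`` around the 50-coin
    reject value with decision noise ``sigma``.  After every accepted trial
    the prediction error updates the weights, the touched variances shrink,
    and the learning rate is re-derived from the remaining uncertainty.
    Rejections teach nothing and leave the state untouched.
    """

    def __init__(
        self,
        model_id: str,
        params: Mapping[str, float],
        node_count: int = DEFAULT_NODE_COUNT,
    ):
        if model_id not in MODELS or MODELS[model_id].kind != "fa":
            raise KeyError(f"not a function-approximation model: {model_id}")
        self.model_id = model_id
        self.params = dict(params)
        self.node_count = node_count
        self.kappa = float(params["kappa"])
        self._bp: BlockParams | None = None

    # -- state ---------------------------------------------------------
    def start_block(self, spec) -> None:
        bp = resolve_block_params(self.model_id, self.params, spec)
        self._bp = bp
        n = self.node_count
        # V = 50 on the first trial: each feature contributes 25
        self.w = np.full((2, n), REJECT_VALUE / 2.0)
        self.v = np.full((2, n), U_INIT)
        self.alpha = np.array([bp.alpha_s0, bp.alpha_f0])

    def _basis(self, slow_deg: float, fast_deg: float) -> np.ndarray:
        return np.stack(
            [
                encode_feature(slow_deg, self.kappa, self.node_count),
                encode_feature(fast_deg, self.kappa, self.node_count),
            ]
        )

    def _value_and_uncertainty(self, x: np.ndarray):
        vals = np.einsum("dn,dn->d", x, self.w)
        uncs = np.einsum("dn,dn->d", x, self.v)
        return vals, uncs

    # -- choice --------------------------------------------------------
    def accept_prob(self, slow_deg, fast_deg, accept_key: int = 0) -> float:
        x = self._basis(slow_deg, fast_deg)
        vals, uncs = self._value_and_uncertainty(x)
        va = accept_value(float(vals.sum()), float(uncs.sum()), self._bp.c)
        return p_accept(va, self._bp.sigma)

    def test_values(self, left, right):
        xl = self._basis(*left)
        xr = self._basis(*right)
        return (
            float(np.einsum("dn,dn->", xl, self.w)),
            float(np.einsum("dn,dn->", xr, self.w)),
        )

    # -- learning ------------------------------------------------------
    def update(self, slow_deg, fast_deg, choice: str, outcome: float) -> None:
        if choice != "accept":
            return
        x = self._basis(slow_deg, fast_deg)
        vals, uncs = self._value_and_uncertainty(x)
        delta = outcome - float(vals.sum())
        for d in range(2):
            self.w[d] += self.alpha[d] * x[d] * delta
            self.v[d] -= self.alpha[d] * x[d] * self.v[d]
        np.maximum(self.v, 0.0, out=self.v)
        bp = self._bp
        if bp.mean_update:
            a = _next_rate(0.5 * float(uncs.sum()), bp.m_s)
            self.alpha[:] = a
        else:
            self.alpha[0] = _next_rate(float(uncs[0]), bp.m_s)
            self.alpha[1] = _next_rate(float(uncs[1]), bp.m_f)


class BanditAgent(_Agent):
    """Scalar Kalman filter that ignores stimulus features entirely."""

    def __init__(self, params: Mapping[str, float]):
        self.c = float(params["c"])
        self.sigma = float(params["sigma"])
        self.alpha0 = float(params["alpha"])
        # one bandit, one feature-free uncertainty estimate
        self.m = measurement_noise(self.alpha0, U_INIT)

    def start_block(self, spec) -> None:
        self.value = REJECT_VALUE
        self.u = U_INIT
        self.alpha = self.alpha0

    def accept_prob(self, slow_deg, fast_deg, accept_key: int = 0) -> float:
        return p_accept(accept_value(self.value, self.u, self.c), self.sigma)

    def update(self, slow_deg, fast_deg, choice, outcome) -> None:
        if choice != "accept":
            return
        u_pre = self.u
        self.value += self.alpha * (outcome - self.value)
        self.u -= self.alpha * self.u
        self.alpha = _next_rate(u_pre, self.m)


class WSLSAgent(_Agent):
    """Win-stay/lose-shift: repeat a rewarded accept, otherwise reject.

    An accept with outcome >= 50 counts as a win (repeat accept with
    probability 1 - epsilon); any other history yields accept with
    probability epsilon.  The first choice of a block is random.
    """

    def __init__(self, params: Mapping[str, float]):
        eps = float(params["epsilon"])
        if not 0.0 <= eps <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        self.eps = eps

    def start_block(self, spec) -> None:
        self.prev_choice: str | None = None
        self.prev_outcome = np.nan

    def accept_prob(self, slow_deg, fast_deg, accept_key: int = 0) -> float:
        if self.prev_choice is None:
            return 0.5
        if self.prev_choice == "accept" and self.prev_outcome >= REJECT_VALUE:
            return 1.0 - self.eps
        return self.eps

    def update(self, slow_deg, fast_deg, choice, outcome) -> None:
        if choice in ("accept", "reject"):
            self.prev_choice = choice
            self.prev_outcome = outcome


class RandomChoiceAgent(_Agent):
    """Feature-blind responding with a fixed bias for accept choices."""

    def __init__(self, params: Mapping[str, float]):
        b = float(params["b_a"])
        if not 0.0 <= b <= 1.0:
            raise ValueError("b_a must lie in [0, 1]")
        self.b_a = b

    def accept_prob(self, slow_deg, fast_deg, accept_key: int = 0) -> float:
        return self.b_a


class RandomKeyAgent(_Agent):
    """Feature-blind responding with a fixed bias for the right response key."""

    def __init__(self, params: Mapping[str, float]):
        b = float(params["b_r"])
        if not 0.0 <= b <= 1.0:
            raise ValueError("b_r must lie in [0, 1]")
        self.b_r = b

    def accept_prob(self, slow_deg, fast_deg, accept_key: int = 0) -> float:
        # accept_key == 1 means the right key maps to accept on this trial
        return self.b_r if accept_key == 1 else 1.0 - self.b_r


def make_agent(model_id: str, params: Mapping[str, float], node_count: int = DEFAULT_NODE_COUNT):
    """Instantiate the agent class registered under ``model_id``."""
    kind = MODELS[model_id].kind
    if kind == "fa":
        return KalmanFALearner(model_id, params, node_count)
    if kind == "bandit":
        return BanditAgent(params)
    if kind == "wsls":
        return WSLSAgent(params)
    if kind == "random_choice":
        return RandomChoiceAgent(params)
    if kind == "random_key":
        return RandomKeyAgent(params)
    raise KeyError(model_id)
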