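"""Group-level model comparison.

Per-participant relative evidence is summarised by AICc weights; group-level
inference uses random-effects Bayesian model selection (RFX-BMS): model
frequencies in the population get a Dirichlet posterior estimated by
variational Bayes, from which exceedance probabilities (XP, the posterior
probability that a model is the most frequent) are sampled.  The Bayes
omnibus risk (BOR) — the posterior probability that all models are equally
frequent — protects the XP against overconfidence:

    PXP_k = XP_k * (1 - BOR) + BOR / K.

Log model evidence is approximated as -AICc/2, so per-participant posterior
model probabilities coincide with AICc weights; all outputs are invariant to
per-participant shifts of the evidence (hence to the choice of baseline
model when working with AICc differences).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["BMSResult", "aicc_weights", "evidence_from_aicc", "random_effects_bms"]


def aicc_weights(aicc_values: Sequence[float], baseline: int | None = None) -> np.ndarray:
    """AICc weights: ``exp(-dAICc/2)`` normalised to sum to 1 per participant.

    ``baseline`` picks the model whose AICc anchors the differences; the
    choice cancels in the normalisation and is accepted only for
    interpretability.  Accepts a vector (one participant) or a
    participants-by-models matrix.
    """
    a = np.asarray(aicc_values, dtype=float)
    squeeze = a.ndim == 1
    a = np.atleast_2d(a)
    ref = a[:, [baseline]] if baseline is not None else np.min(a, axis=1, keepdims=True)
    log_w = -0.5 * (a - ref)
    w = np.exp(log_w - logsumexp(log_w, axis=1, keepdims=True))
    return w[0] if squeeze else w


def evidence_from_aicc(aicc_matrix: np.ndarray) -> np.ndarray:
    """Log model evidence approximation: -AICc/2, per participant and model."""
    return -0.5 * np.asarray(aicc_matrix, dtype=float)


@dataclasses.dataclass(frozen=True)
class BMSResult:
    """Random-effects BMS output."""

    alpha: np.ndarray  # Dirichlet posterior concentrations, one per model
    expected_frequencies: np.ndarray
    xp: np.ndarray  # exceedance probabilities
    bor: float  # Bayes omnibus risk
    pxp: np.ndarray  # protected exceedance probabilities
    posterior: np.ndarray  # per-participant model attribution (n x K)
    n_iterations: int


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL divergence KL(Dir(alpha) || Dir(alpha0))."""
    asum, a0sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(asum)
        - gammaln(alpha).sum()
        - gammaln(a0sum)
        + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(asum)))
    )


def random_effects_bms(
    evidence: np.ndarray,
    alpha0: float = 1.0,
    n_xp_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-10,
) -> BMSResult:
    """Variational random-effects BMS over a participants-by-models log-evidence matrix.

    Iterates the Dirichlet update from a uniform prior (``alpha0`` per model)
    to convergence, estimates XP by Monte-Carlo sampling of the posterior
    (100 000 draws keeps the standard error below 0.005), computes the BOR
    from the free-energy comparison of the null model (all frequencies equal)
    against the alternative, and mixes the two into protected XP.
    """
    L = np.asarray(evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("evidence must be a participants-by-models matrix, K >= 2")
    if not np.all(np.isfinite(L)):
        raise ValueError("evidence entries must be finite")
    n, K = L.shape
    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    g = np.full((n, K), 1.0 / K)
    for it in range(1, max_iter + 1):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError("random-effects BMS did not converge")
    freq = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_xp_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=K) / n_xp_samples

    # free energy of the alternative (frequencies vary) ...
    f1 = (
        float(np.sum(g * (L + digamma(alpha) - digamma(alpha.sum()))))
        - float(np.sum(g * np.log(np.clip(g, 1e-300, None))))
        - _dirichlet_kl(alpha, a0)
    )
    # ... versus the null (all models equally frequent)
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = xp * (1.0 - bor) + bor / K
    return BMSResult(
        alpha=alpha,
        expected_frequencies=freq,
        xp=xp,
        bor=bor,
        pxp=pxp,
        posterior=g,
        n_iterations=it,
    )
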