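"""Descriptive and inferential statistics on trial logs.

Covers the behavioural analysis layer: per-participant condition summaries
(cumulative reward gain relative to the 50-coins-per-trial chance baseline,
learning and test accuracy), paired condition contrasts with Cohen's d,
fixed-effect meta-analysis with Hedges' g and Cochran's Q, the binomial
performance-exclusion rule, and the analytic power of a paired t-test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "summarise",
    "learning_curves",
    "paired_contrast",
    "ContrastResult",
    "fixed_effect_meta",
    "MetaResult",
    "exclusion_threshold",
    "power_paired_t",
    "holm_adjust",
]


def summarise(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Per-participant condition summary.

    One row per participant with, separately for slow and fast blocks: mean
    per-block cumulative reward gain (summed outcomes of responded learning
    trials minus 50 per trial), mean learning accuracy and mean test
    accuracy.  No-response trials are excluded throughout.
    """
    rows = []
    for participant, plog in trial_log.groupby("participant", sort=True):
        entry: dict = {"participant": participant}
        for cond in ("slow", "fast"):
            clog = plog[plog["condition"] == cond]
            gains = []
            for _, blog in clog.groupby("block"):
                learn = blog[(blog["phase"] == "learning") & (blog["choice"] != "none")]
                if len(learn):
                    gains.append(learn["outcome"].sum() - 50.0 * len(learn))
            learn = clog[(clog["phase"] == "learning") & (clog["choice"] != "none")]
            test = clog[(clog["phase"] == "test") & (clog["choice"] != "none")]
            entry[f"gain_{cond}"] = float(np.mean(gains)) if gains else np.nan
            entry[f"learn_acc_{cond}"] = float(learn["correct"].mean()) if len(learn) else np.nan
            entry[f"test_acc_{cond}"] = float(test["correct"].mean()) if len(test) else np.nan
            entry[f"accept_prop_{cond}"] = (
                float((learn["choice"] == "accept").mean()) if len(learn) else np.nan
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """Average over 3 adjacent values (shorter windows at the edges)."""
    out = np.empty_like(y, dtype=float)
    for i in range(len(y)):
        lo, hi = max(0, i - 1), min(len(y), i + 2)
        out[i] = np.nanmean(y[lo:hi])
    return out


def learning_curves(trial_log: pd.DataFrame, smooth: bool = True) -> pd.DataFrame:
    """Accept proportion and accuracy per learning trial and condition,
    averaged over participants and blocks, optionally smoothed over 3
    adjacent trials."""
    learn = trial_log[(trial_log["phase"] == "learning") & (trial_log["choice"] != "none")]
    rows = []
    for cond, grp in learn.groupby("condition"):
        by_trial = grp.groupby("trial").agg(
            accept=("choice", lambda c: float((c == "accept").mean())),
            accuracy=("correct", "mean"),
        )
        acc = by_trial["accuracy"].to_numpy(dtype=float)
        acp = by_trial["accept"].to_numpy(dtype=float)
        if smooth:
            acc, acp = _smooth3(acc), _smooth3(acp)
        for trial, a, p in zip(by_trial.index, acc, acp):
            rows.append(dict(condition=cond, trial=int(trial), accuracy=a, accept=p))
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class ContrastResult:
    t: float
    df: int
    p: float
    cohen_d: float
    degenerate: bool  # zero-variance differences: t/d not well defined


def paired_contrast(
    values_a: Sequence[float],
    values_b: Sequence[float],
    sided: str = "greater",
) -> ContrastResult:
    """Paired t-test of ``a`` against ``b`` with Cohen's d for paired data.

    ``sided`` is "greater" (one-sided, a > b), "less", or "two-sided".
    Cohen's d is the mean difference over the standard deviation of the
    differences.  Zero-variance differences are flagged degenerate: equal
    vectors give t = 0 (one-sided p = 0.5), a constant non-zero shift gives
    an infinite t.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length paired vectors, n >= 2")
    diff = a - b
    df = len(a) - 1
    sd = diff.std(ddof=1)
    if sd == 0.0:
        m = diff.mean()
        if m == 0.0:
            p = 0.5 if sided in ("greater", "less") else 1.0
            return ContrastResult(0.0, df, p, 0.0, True)
        t = np.inf if m > 0 else -np.inf
        if sided == "greater":
            p = 0.0 if m > 0 else 1.0
        elif sided == "less":
            p = 0.0 if m < 0 else 1.0
        else:
            p = 0.0
        return ContrastResult(float(t), df, p, float("nan"), True)
    res = sps.ttest_rel(a, b, alternative=sided if sided != "two-sided" else "two-sided")
    d = float(diff.mean() / sd)
    return ContrastResult(float(res.statistic), df, float(res.pvalue), d, False)


@dataclasses.dataclass(frozen=True)
class MetaResult:
    g: np.ndarray  # per-study Hedges' g
    se: np.ndarray  # per-study standard errors
    pooled_g: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float  # Cochran's Q
    i2: float  # heterogeneity, percent
    tau2: float  # 0 under the fixed-effect model


def fixed_effect_meta(per_study: Sequence[tuple[float, int]]) -> MetaResult:
    """Fixed-effect meta-analysis of paired standardised mean differences.

    Each study enters as (Cohen's d, n pairs).  The small-sample correction
    ``J = 1 - 3/(4 df - 1)`` turns d into Hedges' g; the paired-design
    variance of g is ``1/n + g^2/(2 n)``; studies are pooled by inverse
    variance.  Cochran's Q tests heterogeneity, reported with
    ``I^2 = max(0, (Q - df) / Q)``; the fixed-effect model fixes tau^2 at 0.
    """
    if len(per_study) < 1:
        raise ValueError("need at least one study")
    d = np.array([x[0] for x in per_study], dtype=float)
    n = np.array([x[1] for x in per_study], dtype=float)
    df = n - 1
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var = 1.0 / n + g**2 / (2.0 * n)
    wts = 1.0 / var
    pooled = float(np.sum(wts * g) / np.sum(wts))
    se_pooled = float(1.0 / np.sqrt(np.sum(wts)))
    z = pooled / se_pooled
    p = 2.0 * sps.norm.sf(abs(z))
    q = float(np.sum(wts * (g - pooled) ** 2))
    dfq = len(per_study) - 1
    i2 = float(max(0.0, (q - dfq) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(
        g=g,
        se=np.sqrt(var),
        pooled_g=pooled,
        ci_low=pooled - 1.959963984540054 * se_pooled,
        ci_high=pooled + 1.959963984540054 * se_pooled,
        z=float(z),
        p=float(p),
        q=q,
        i2=i2,
        tau2=0.0,
    )


def exclusion_threshold(n_trials: int, p_success: float, percentile: float = 0.975) -> int:
    """Smallest success count k with Binomial CDF(k; n, p) >= percentile.

    Participants whose accuracy is at or below ``k / n_trials`` are
    indistinguishable from chance-level responding at the given percentile
    and are excluded.
    """
    if n_trials < 1 or not 0.0 < p_success < 1.0 or not 0.0 < percentile < 1.0:
        raise ValueError("invalid binomial threshold arguments")
    return int(sps.binom.ppf(percentile, n_trials, p_success))


def power_paired_t(n: int, d: float, alpha: float = 0.05, sided: str = "one") -> float:
    """Analytic power of a paired t-test for effect size d with n pairs.

    Uses the noncentral t distribution with noncentrality ``d * sqrt(n)`` and
    ``n - 1`` degrees of freedom.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    df = n - 1
    nc = d * np.sqrt(n)
    if sided == "one":
        tcrit = sps.t.ppf(1.0 - alpha, df)
        return float(sps.nct.sf(tcrit, df, nc))
    if sided == "two":
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    raise ValueError("sided must be 'one' or 'two'")


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
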