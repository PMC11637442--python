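"""Behavioural statistics on a simulated cohort.

Summarises per-participant condition differences, tests them with a paired
one-sided t-test, pools effect sizes across (mock) samples with a
fixed-effect meta-analysis, and reproduces the design's exclusion threshold
and power analysis.
"""

import pandas as pd

from slowrl import (
    SessionConfig,
    build_session,
    exclusion_threshold,
    fixed_effect_meta,
    paired_contrast,
    power_paired_t,
    simulate_choices,
    summarise,
)

logs = []
params = dict(kappa=6.0, c=6.0, sigma=42.0, alpha_S=0.6, alpha_F=0.4)
for i in range(20):
    session = build_session(SessionConfig(), seed=400 + i, participant=f"sim{i:02d}")
    logs.append(simulate_choices("2LRc", params, session, seed=500 + i))
cohort = summarise(pd.concat(logs, ignore_index=True))

r = paired_contrast(cohort["gain_slow"], cohort["gain_fast"], sided="greater")
print(f"mean gain per block: slow {cohort['gain_slow'].mean():.1f}, "
      f"fast {cohort['gain_fast'].mean():.1f} coins")
print(f"paired one-sided t({r.df}) = {r.t:.2f}, p = {r.p:.4f}, d = {r.cohen_d:.2f}")

meta = fixed_effect_meta([(r.cohen_d, len(cohort)), (0.31, 50), (0.22, 50)])
print(f"\nfixed-effect meta-analysis over three samples: pooled Hedges' g = "
      f"{meta.pooled_g:.3f} [{meta.ci_low:.3f}, {meta.ci_high:.3f}], "
      f"Q = {meta.q:.2f}, I^2 = {meta.i2:.1f}%")

k = exclusion_threshold(120, 0.5, 0.975)
print(f"\nchance-performance exclusion: <= {k}/120 correct "
      f"({100 * k / 120:.1f}%) at the binomial 97.5th percentile")
print(f"power of a one-sided paired t-test, d = 0.26, n = 160: "
      f"{power_paired_t(160, 0.26):.3f}")
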