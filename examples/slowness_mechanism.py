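"""Show which learning-rate structures can express a slowness advantage.

Simulates the four Kalman-filter learners over 100 sessions with a higher
learning rate for the slow than the fast feature (0.6 vs 0.3; the four-rate
model's relevant rates are raised by 0.1) and contrasts cumulative reward
gain between slow and fast blocks.  Only models with separate rates can turn
the rate asymmetry into a performance asymmetry.
"""

from slowrl import SessionConfig, build_session, simulate_gains, paired_contrast

sessions = [build_session(SessionConfig(), seed=100 + i) for i in range(100)]
base = dict(kappa=6.0, c=6.0, sigma=42.0)
settings = {
    "1LR": dict(base, alpha=0.3),
    "2LRf": dict(base, alpha_S=0.6, alpha_F=0.3),
    "2LRc": dict(base, alpha_S=0.6, alpha_F=0.3),
    "4LR": dict(base, alpha_SR=0.7, alpha_FR=0.4, alpha_SI=0.6, alpha_FI=0.3),
}

print("model  gain(slow)  gain(fast)  diff   paired-t one-sided p")
for model, params in settings.items():
    g = simulate_gains(model, params, sessions, seed=7)
    per = g.groupby(["session", "condition"])["gain"].mean().unstack()
    r = paired_contrast(per["slow"], per["fast"], sided="greater")
    print(f"{model:>5}  {per['slow'].mean():>10.1f}  {per['fast'].mean():>10.1f}"
          f"  {per['slow'].mean() - per['fast'].mean():>5.1f}   p = {r.p:.4f}")
print("\nA small p means reliably more reward in slow blocks. The one-rate "
      "model cannot express the asymmetry, so its difference hovers near 0.")
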