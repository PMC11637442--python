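# Methods

This note documents the models, the synthetic-task generator, the numerical
choices, and the places where the design was genuinely open and we had to
commit to one reading.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task generator

The generator emulates a two-feature accept-reject bandit.  Per session:
eight blocks; per block a 15-position grid (24° steps) with a block-specific
offset (multiples of 3°, all eight offsets distinct), three phases
(observation 30, learning 60, test 36 trials; a shorter variant with 0/45/15
trials and a 13-coin minimum test difference is available via
`SessionConfig.short_variant`).  Counterbalancing: each (feature-speed ×
relevant-dimension) cell occurs twice, once per session half; each
maximum-reward position (10°, 100°, 190°, 280°) is used once per relevant
dimension.  Reward is `(180 − d)/180 × 100` coins, piecewise-linear in the
circular distance `d` to the maximum-reward position.  Rewards are kept
real-valued; `round_outcomes` optionally rounds displayed outcomes, which
changes nothing at the tolerances used anywhere in the package.

**Slow feature.**  The slow sequence is a zero-mean Gaussian random walk
(SD 30°, drift-free; a walk attracted to angle 0 would confound the reward
manipulation) reconciled with the design constraint that every grid position
appears exactly once per 15-trial cycle: each trial proposes the previously
*shown* angle plus a Gaussian step and shows the nearest not-yet-used grid
position.  Proposing from the shown angle (rather than a free-running latent
walk) is deliberate: in the small-step limit it degenerates to a
nearest-unused-neighbour sweep with small steps, whereas a free-running
latent would ring outward with growing steps, which contradicts the intent
of a slow feature.

**Fast feature.**  Uniform draws among the unused positions of the cycle,
excluding steps of exactly one grid spacing (and zero, across cycle
boundaries); cycles that become unsatisfiable are resampled.  The allowed
step distances (48°–168°) occur at near-uniform rates.

**Test pairs.**  The exact schedule of test-phase value differences is not
fixed by the design beyond its range; the generator stratifies the absolute
value difference into six uniform bins spanning [2, 54] coins, draws pairs
of relevant angles from the 12°-offset test grid accordingly, samples
irrelevant angles uniformly from the same grid, and randomises left/right.
This is an approximation to an unpublished schedule and is flagged as such.

**What the generator does not emulate.**  Perceptual properties of the real
shape/colour spaces (angles are abstract and exactly uniform), reaction
times, no-response trials (the schema allows `choice = none` so recorded
data can be ingested, but the simulator never produces them), and
session-level fatigue or learning-to-learn across blocks.  Tests passing on
this generator therefore validate the algorithmic pipeline, not claims
about perception or motivation in real data.

## Learning models

Stimuli are encoded per feature dimension as normalised von Mises profiles
over a node bank; value is linear in the encoding, uncertainty is tracked
per node and the learning rate is derived from it (Kalman filter; see the
README for the equations).  Initialisation: weights 25 per node and
variances 5 per node, so that on the first trial of every block `V = 50`
(the reject value) and the uncertainty bonus is 5 per feature (10 total).
The measurement noise is set per learning-rate slot as
`M = 5(1 − α₀)/α₀`, the inversion of the rate recursion at the initial
uncertainty, so the first-trial rate equals the fitted value; `α₀ = 0` maps
to infinite noise (no learning) and `α₀ = 1` to zero noise (full steps).

**Basis resolution.**  The default is 15 nodes per feature dimension
(a 30-dimensional stimulus vector), anchored at 0°, 24°, …, 336° for all
blocks, with the normalisation over the node set; `node_count` is
configurable (e.g. 360).  The choice is forced by the learning dynamics:
with a sum-normalised basis the effective per-trial value step at the
stimulus scales with `x·x`, which is ≈ 0.3 for 15 nodes but ≈ 0.01 for 360
nodes at concentrations in the plausible range — with 360 nodes the model
cannot learn the task within a block at any such κ, while with 15 nodes the
documented dynamics (rapid early learning, declining accept rates,
generalisation to off-grid test angles) emerge.  Off-node stimulus angles
(grid offsets are multiples of 3°) are encoded exactly by the same formula;
no node needs to sit on the stimulus.  The block grid offset changes `x·x`
only marginally, so anchoring the nodes absolutely rather than per block is
immaterial.

**Uncertainty aggregation.**  `U` is computed per feature dimension and the
two are *summed* in the choice bonus (initial bonus 10 = 5 + 5).  Models
with one rate per block (`1LR`, `2LRc`) update that rate from the *mean* of
the two per-feature uncertainties; models with per-feature rates (`2LRf`,
`4LR`) update each rate from its own feature's uncertainty.  The rate used
on trial t is the one produced by the update after the previous accepted
trial; `α_{t+1} = U_t/(U_t + M)` uses the uncertainty computed at choice on
trial t (before the variance update).

**Updates happen only on accepts.**  Rejections pay a known constant and
carry no information about the stimulus; weights, variances and rates are
all left untouched on reject and no-response trials.

**Nesting structure.**  Tied-rate models collapse exactly onto the nested
sibling with the same rate propagation: `4LR` with all rates equal is
bit-identical to `2LRf` with tied rates, and `2LRc` with tied rates to
`1LR`.  Across the two groups (per-feature vs mean update) the collapse is
exact only when the two per-feature uncertainties coincide — e.g. under a
uniform basis (κ = 0) — because the mean- and per-feature rate updates then
agree.  The test suite asserts exactly these identities.

**Test phase.**  Fits never use test trials.  For simulation, the model
chooses the stimulus with the higher `V` (no bonus, no feedback, no update),
ties broken uniformly — so feature-blind models sit at exactly 50%.

**Controls.**  The bandit keeps a single value (initialised at 50) and
uncertainty (initialised at 5, by analogy with one feature; the design does
not pin this down) with the same choice rule.  WSLS treats an accept with
outcome ≥ 50 as a win; its first choice in a block is random, and after a
reject it switches to accept with probability ε.  The random-key model
needs the per-trial accept-key mapping, which the trial log carries.

## Likelihood and fitting

The NLL is summed over responded learning trials with the model state reset
at each block start; per-trial probabilities are clipped to
[1e-12, 1 − 1e-12] so the NLL is finite everywhere in the search box.
Optimisation uses `scipy.optimize.direct` (DIRECT-L, deterministic) with a
default budget of 10,000 evaluations followed by a bounded Nelder-Mead
polish; out-of-box probes during the polish are clipped to the bounds.
Parameter boxes (a documented choice; the originals are unpublished):
α ∈ [0, 1], κ ∈ [0, 30], c ∈ [0, 20], σ ∈ [1, 150], and [0.001, 0.999] for
the heuristic probabilities.  These comfortably contain the empirically
plausible region.  AICc uses the number of responded learning trials as N.

The reward-maximising search optimises the mean simulated per-block gain
over 16 pre-built sessions with common random numbers across probes, so the
optimiser sees a deterministic objective; reported performance is then
evaluated on fresh sessions.

A compiled (numba) fast path runs the per-block forward pass; the readable
step-by-step agent classes are the reference semantics and the test suite
asserts agreement between the two to 1e-9 for every model.

## Model selection

Log model evidence is approximated as −AICc/2, which makes per-participant
posterior model probabilities equal AICc weights and renders every
downstream quantity invariant to per-participant evidence shifts (hence to
the choice of a baseline model).  Group-level inference is variational
random-effects BMS with a uniform Dirichlet prior (α₀ = 1 per model),
iterated to a 1e-10 fixed point.  Exceedance probabilities are estimated
from 100,000 Dirichlet draws (Monte-Carlo SE < 0.005); the Bayes omnibus
risk compares the variational free energy of the alternative against the
null of equal frequencies, and protected exceedance probabilities mix the
two: `PXP = XP(1 − BOR) + BOR/K`.

## Recovery harnesses

Parameter recovery simulates subjects with parameters from a documented
uniform sampler (α ~ U(0.1, 0.9) per slot; κ, c ~ U(2, 10); σ ~ U(20, 60);
heuristic probabilities over their plausible ranges), fits the generating
model, and correlates true with recovered values per parameter;
zero-variance ground truth yields an undefined (NaN) correlation rather
than a number.  Model recovery fits all candidate models to each simulated
subject and selects per subject by lowest AICc; the confusion matrix is
row-normalised.  Because the learning models are nested, draws with nearly
tied rates are genuinely indistinguishable from the smaller model and the
AICc penalty then correctly prefers it; recovery quality is therefore a
property of the sampler as much as of the fitting machinery.

## Problem sizes and budgets in the shipped checks

The test suite and acceptance script scale the studies to remain
desk-runnable while keeping estimates stable: recovery uses 50 subjects per
model at reduced DIRECT budgets (600–3,000 evaluations; the polish makes
the NLL optimum insensitive to the exact budget at these sizes), model
recovery 30 subjects per generating model, the slowness-mechanism contrast
200 sessions, the chance-level benchmark 1,000 test phases, and the
reward-maximising search a 120-evaluation DIRECT stage over 16 sessions.

## Known limitations

* The learning-rate structures know from trial 1 which feature is slow and
  which is relevant; they describe, rather than explain, how such knowledge
  is acquired.
* The test-pair difference schedule approximates an unpublished design.
* Identification of the two-rate models degrades smoothly as the sampled
  rates approach each other or decision noise grows; see the recovery
  harness for quantification.
* The variational BMS is an approximation; its symmetric- and
  strong-evidence limits are exercised by the tests, but small-cohort
  omnibus risks are only asymptotically 1 under the null.
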