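# Methods

`rmlsim` implements a meta-reinforcement-learning agent — the Reinforcement
Meta-Learner (RML) — in which the intensity of cognitive control is itself a
learned decision, together with three simulated experiments and the analysis
pipeline that turns their trial logs into simulated medial-prefrontal (MPFC /
dACC) activity profiles.  This note documents the model, the design choices
made where the architecture was genuinely open, the calibration of defaults,
and what the simulations do and do not show.

## The agent

**Value learning.**  Every value the agent tracks — option values in the
action module, boost action values in the control module — is a scalar
Kalman filter: mean `m`, estimation variance `u`, assumed outcome variance
`r`.  An outcome `z` updates `m ← m + k·(z − m)` with gain
`k = u/(u + r)` and `u ← (1 − k)·u` (plus an optional process-noise term,
zero by default since all three tasks are stationary).  The filters start
from a diffuse, optimistic prior: prior mean equal to the largest attainable
reward in the task, prior variance large.  With softmax action selection the
prior mean is the only exploration mechanism, so "optimistic" must mean
*above* attainable net value; a mid-range prior leaves better-than-average
states unexplored (we verified this in pilot runs, where it produced flat
boost policies).

**Boost (cognitive control).**  Before each decision the agent selects a
discrete boost level `b ∈ {1, …, 10}` by softmax over the Kalman-learned
q-values of the condition visible at trial onset (the trial-type pair in the
speeded task, the load cue in WM, the compound context-bandit cue in
foraging).  Boost carries a linear intrinsic cost `c·b`; q-values are
learned on net outcomes (reward − cost), so the policy directly maximizes
net value.  Because boost is an *ordered intensity*, one trial's outcome is
informative about neighboring levels: updates are spread over the level axis
with a Gaussian kernel (width 2.5 levels) implemented as reliability
discounting (kernel weight `w` inflates the observation noise to `r/w`).
Without this generalization, 10 levels × 36–128 conditions cannot be learned
within the sessions' printed lengths.

**Neuromodulation.**  The selected boost drives two bounded, affine,
non-decreasing outputs: LC (gain/urgency; range 0–1) and VTA (reward-signal
scaling; neutral at 1.0 by default, so outcomes reach the value filters
unscaled unless VTA modulation is enabled in the config).  LC is the sole
interface between the agent and the task modules: it shrinks diffusion
boundaries, discounts the foraging engage bias, and raises the WM network's
gain.

**Surprise.**  Unsigned prediction error `|z − m|`.  The speeded-task
analysis additionally uses trial-type surprise: |trial total reward − the
session's long-term mean total| (which is exactly 9 for the balanced 6×6
design).

## Task modules

### Speeded decision-making

36 ordered pairs of options with integer rewards 2–7 (two fractal stimuli
per reward level), 54 repetitions each (1944 trials).  Stimulus values are
pretrained (30 observations each) before the session.  Per trial the learned
value difference δv sets the diffusion drift (`drift = 0.013·δv` per cycle),
LC shrinks the boundary from 160 down toward a floor of 10 (85% shrink at
maximum LC), and one Euler step of unit dt is one "DDM cycle" with unit
per-cycle noise.  The chosen option's reward is devalued linearly in RT
(full at 0, zero at the 14000-cycle deadline; timeouts earn nothing) and
feeds back into both the chosen stimulus' value and the boost q-value.

The regime of interest — the W-shaped composed signal — arises when boost
saturates high for |δv| ≤ 1 (deadline pressure makes control worth its cost)
and falls off over |δv| = 2…5 (fast trials gain little from tighter
boundaries).  Boundary, drift scale and cost rate (0.19/level) were
calibrated by pilot simulation to this regime and then frozen.  Note the
geometry of the "W": a quartic with positive leading and negative quadratic
coefficients has a local *maximum* at zero flanked by two minima — the
letter-W profile — and that is what the composed (value + boost) curve
shows: the boost dome rides on top of the U-shaped net value curve.

### Verbal working memory

Loads {1, 4, 6, 8} words from a 16-word lexicon, 90 trials per load, 50%
match probes, correct/incorrect feedback delivered as reward 1/0.  The
task module is a dual-layer competitive recurrent network: a phonological
input layer (one unit per word) whose trace decays during the 10-s delay
(50 steps of 0.2 s), and an articulatory output layer with
gain-modulated, thresholded self-excitation, a small spontaneous baseline
drive, and a shared saturating lateral-inhibition pool.  A word survives the
delay only if its output unit reaches the self-sustaining rehearsal
attractor; the inhibition pool caps how many units can rehearse at once, and
because self-excitation is gain-modulated that capacity grows roughly
linearly with LC output.  Gain therefore buys list capacity — which is why
the learned boost increases near-linearly with load — while two error
sources remain irreducible: an encoding lapse per word (P = 0.22,
load-independent, unrecoverable at any gain) and spontaneous baseline
activity that at low loads (little inhibition) occasionally drifts a lure
unit across the criterion.  Together these hold accuracy near 87% at each
load's learned operating point.

The match criterion is calibrated once per participant on a held-out block
(400 trials at mid LC) and frozen.  Each participant also completes an
unrecorded practice phase (90 trials/load) so the recorded session reflects
the converged policy, as it would for human participants trained before
scanning.  Participants differ in capacity (inhibition weight,
SD 0.004) and lapse rate (SD 0.04) — without such heterogeneity, 15
identical simulated subjects make one-sample t-tests flag microscopically
small load trends in the surprise and value regressors.

### Foraging

16 contexts (patches) × 8 two-armed bandits; the optimal-arm rewards form a
global even grid on [2, 7], dealt to contexts by stratified assignment so
that every context spans most of the value range while the 16 context means
remain distinct and ordered.  The means are then contracted toward the
global mean (`context_spread = 0.75`): with full-strength context means the
proposed bandit's value tracks the patch value so tightly that choice
difficulty is constant across foraging value, and the characteristic
rise-then-fall of the control signal cannot exist; partial decoupling
mirrors the factorial independence of engage and forage values in the
source paradigms.  The forage option's value at a cue is the context mean
excluding the proposed bandit, minus the forage cost (0.1).

Per proposal: boost is selected from the compound cue; δv = learned engage
value − learned forage value sets the drift (scale 0.05); LC shrinks the
boundary (60 → floor 8) and discounts the engage starting-point bias
(bias₀ = 2); deadline 2000 cycles, abort unrewarded.  Engaging plays the
cued bandit with the agent's softmax arm policy (suboptimal arm = optimal −
2); foraging pays the waiting cost and redraws a different bandit uniformly
from the same context, with at most 20 consecutive forages.  Boost q-values
learn from a one-step bootstrapped return (immediate outcome, plus the
better learned option value of the redrawn cue after a forage); Monte-Carlo
trial returns were too noisy for the forage-side q-landscapes to converge
within the session.  Engage, forage and arm values are pretrained (25
observations each; forage values from one-step lookahead samples), matching
the protocol of training the agent on all bandits in all contexts before
the task.

## Analysis

Trial records are binned within participant and then averaged across
participants: by the 11 value-difference levels (speeded), by load (WM), or
by pooled-quantile bins of foraging value / choice difficulty (8 bins each).
The composed dACC signal is task-specific: net value + boost (speeded),
boost (WM), boost with a boost+value composite variant (foraging).
Polynomial shape comparisons use least squares on the group-mean curve with
AIC = n·ln(RSS/n) + 2k, k = degree + 2 (coefficients plus noise variance;
AICc available as a toggle), and Akaike weights
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.  Linear trends are tested with a
one-sample t-test on per-participant regression slopes; the WM load effect
on accuracy with the textbook repeated-measures one-way ANOVA, reporting its
own degrees of freedom (3, 42 for 15 participants × 4 loads).

## Numerical and reproducibility notes

* One seeded generator per participant, seed = base_seed + participant
  index; every record row carries its seed, and (config, base seed)
  reproduces every output byte (manifests carry SHA-256 checksums).
* The diffusion kernel draws noise in chunks of 2048 cycles and scans the
  cumulative path, so a run costs O(RT); absorption is "first cycle at or
  beyond the boundary".  The Wiener closed form used as a test oracle
  applies when boundaries are large relative to the per-cycle step;
  single-step overshoot biases absorption at boundaries of order one noise
  unit, which is why oracle grids use boundaries of 40–80 noise units.
* Exact q-value ties are resolved by the softmax sampler itself; softmax is
  computed with max-subtraction for stability; degenerate ANOVA tables
  (zero error variance and zero condition variance) return F = 0.
* Problem sizes used by the acceptance script: speeded 80 participants ×
  1944 trials, WM 15 × 360 (the printed design), foraging 24 participants ×
  9 blocks (2304 trials).  The full printed designs (200 and 40
  participants, 18 blocks) are the config defaults and run in a few minutes.

## Limitations

* All model constants are calibrated, not inherited: the antecedent
  implementations' exact parameter values were not available, so defaults
  were set by pilot simulation to the operating regime the experiments
  define (deadline-pressured decisions, capacity-limited rehearsal,
  patch-leaving trade-offs) and then frozen.  Quantities that depend
  delicately on those constants — in particular the *magnitude* of the WM
  boost-trend t statistic, which reflects how consistent the learned
  policies are across 15 simulated participants — land at t ≈ 4–8 here,
  significant and positive but smaller than values a differently
  parameterized agent could produce.
* The synthetic tasks idealize their human counterparts: deterministic
  stimulus–reward mappings, no serial-position or phonological-similarity
  structure in WM, no inter-trial dynamics or fMRI timing.  Passing tests
  show the model reproduces the *computational* signatures (shapes and
  significance patterns of the simulated signals), not BOLD amplitudes or
  anatomical claims.
* The alternative accumulator variant (dual attractor network) and the
  intrinsic-motivation variant of the agent are out of scope; the module
  boundaries would admit either as a drop-in task module.
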