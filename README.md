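# rmlsim

Simulations of the **Reinforcement Meta-Learner (RML)** — a
meta-reinforcement-learning agent in which the intensity of cognitive
control ("boost") is itself learned by reinforcement to maximize net value
(reward minus control cost).  The package is for computational
neuroscientists who want to reproduce, probe or extend the model's account
of dorsal anterior cingulate (dACC) / medial prefrontal (MPFC) activity as
a mixture of value, control and surprise signals.

## The model in brief

The agent tracks every expected value with a scalar Kalman filter
(mean *m*, variance *u*, outcome noise *r*):

```
k = u / (u + r),   m ← m + k (z − m),   u ← (1 − k) u
```

Two value stores mirror two MPFC modules: an *action* module holding option
values, whose difference δv drives choices, and a *boost* module holding
one value per (condition, boost level).  At each decision the agent samples
a discrete boost level b by softmax over those values; boost costs `c·b`
and drives two simulated neuromodulatory nuclei — LC (gain/urgency) and VTA
(reward scaling, neutral by default).  LC is the interface to three task
modules:

* **Speeded decisions** — a drift-diffusion process: drift = `k_d · δv`,
  boundary shrunk by LC, rewards devalued linearly in RT with a
  14000-cycle deadline.
* **Verbal working memory** — a competitive recurrent network whose
  rehearsal capacity grows with LC-modulated gain; loads {1, 4, 6, 8},
  match/non-match probes.
* **Foraging** — 16 patches × 8 two-armed bandits; engage the proposed
  bandit or pay a cost to forage for another; LC tightens boundaries and
  discounts the engage bias; 2000-cycle deadline.

The analysis pipeline bins trial logs by condition, composes the simulated
dACC signal per task (value + boost; boost; boost with a boost+value
composite), compares polynomial shapes with AIC / Akaike weights, and runs
slope t-tests and a repeated-measures ANOVA.  `docs/methods.md` has the
full model description and design rationale.

## Worked example

Simulate three working-memory participants and print the summary
statistics:

```
$ rmlsim run wm --participants 3 --seed 0 --out results/demo
{
  "accuracy_pct": 88.61111111111111,
  "accuracy_by_load": {"1": 0.904, "4": 0.904, "6": 0.867, "8": 0.870},
  "boost_trend": {"df": 2, "mean_slope": 0.5006, "t": 25.35, "p": 0.00155},
  "load_anova": {"F": 1.0, "df1": 3, "df2": 6, "p": 0.455},
  "surprise_trend": {"t": 1.40, "p": 0.296},
  "value_trend": {"t": -1.04, "p": 0.407},
  ...
}
```

Reading this: pooled accuracy sits near 87% and is statistically flat
across loads (`load_anova`), while the boost the agent learns to deploy
*rises* with load (`boost_trend`: mean slope ≈ 0.5 levels per word,
positive t) — the model pays for a harder memory task with more control,
not with errors — and neither surprise nor value expectation trends with
load.  `results/demo/` also receives the full trial records
(`wm_records.csv`, one row per trial with a documented header), the binned
regressor table, and a manifest with config snapshot and checksums; the
same (config, seed) reproduces every byte.

The other tasks run the same way (`rmlsim run speeded`, `rmlsim run
foraging`, or `rmlsim reproduce-all`); the library entry points are
`rmlsim.simulate_task` and the `*_statistics` functions.

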