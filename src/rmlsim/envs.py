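"""Task environments: trial designs, reward rules and state transitions.

Three designs are implemented exactly as specified by the simulated studies:

* speeded decision-making — all 36 ordered pairs of two options with integer
  rewards 2..7 (two fractal stimuli per reward level), linear reward
  devaluation with reaction time and a 14000-cycle deadline;
* verbal working memory — word lists at loads {1, 4, 6, 8} with 50% match
  probes, 90 repetitions per load;
* foraging — 16 contexts (reward patches) of 8 two-armed bandits each; every
  trial proposes one (context, bandit) compound cue and the agent engages it
  or forages for a different bandit from the same context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ForagingTaskConfig, SpeededTaskConfig, WMTaskConfig
from .wm import WMTrialSpec

__all__ = [
    "SpeededTrial",
    "ForagingEnv",
    "generate_speeded_trials",
    "generate_wm_trials",
    "reward_devaluation",
]


@dataclass(frozen=True)
class SpeededTrial:
    """One speeded trial: two options with hidden integer rewards.

    ``left_stim`` / ``right_stim`` index the 12 fractal stimuli (two per
    reward level); ``value_difference`` = left - right in reward units.
    """

    left_reward: int
    right_reward: int
    left_stim: int
    right_stim: int

    @property
    def value_difference(self) -> int:
        return self.left_reward - self.right_reward

    @property
    def total_reward(self) -> int:
        return self.left_reward + self.right_reward


def speeded_stimulus_values(cfg: SpeededTaskConfig) -> np.ndarray:
    """Reward value of each of the 12 stimuli (two fractals per level)."""
    levels = np.arange(cfg.reward_min, cfg.reward_max + 1)
    return np.repeat(levels, 2).astype(float)


def generate_speeded_trials(
    reps_per_type: int, cfg: SpeededTaskConfig, rng: np.random.Generator
) -> list[SpeededTrial]:
    """Shuffled sequence with each of the 36 (left, right) types exactly
    ``reps_per_type`` times.

    Side balance is inherent: every ordered pair appears, so each unordered
    pair occurs equally often on both sides.  The fractal shown for a reward
    level is drawn at random between the level's two stimuli.
    """
    if reps_per_type < 1:
        raise ValueError("reps_per_type must be >= 1")
    levels = np.arange(cfg.reward_min, cfg.reward_max + 1)
    trials = []
    for _ in range(reps_per_type):
        for lv in levels:
            for rv in levels:
                ls = 2 * (lv - cfg.reward_min) + rng.integers(2)
                rs = 2 * (rv - cfg.reward_min) + rng.integers(2)
                trials.append(
                    SpeededTrial(
                        left_reward=int(lv),
                        right_reward=int(rv),
                        left_stim=int(ls),
                        right_stim=int(rs),
                    )
                )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def reward_devaluation(reward: float, rt_cycles: int, deadline: int) -> float:
    """Linear devaluation of reward with reaction time.

    Full reward at rt 0, zero at or after the deadline (timeouts earn
    nothing); linear interpolation in between.
    """
    if rt_cycles < 0:
        raise ValueError("rt_cycles must be non-negative")
    return float(reward) * max(0.0, 1.0 - rt_cycles / deadline)


def generate_wm_trials(
    reps_per_load: int, cfg: WMTaskConfig, n_units: int, rng: np.random.Generator
) -> list[WMTrialSpec]:
    """Shuffled WM session: each load ``reps_per_load`` times, matches
    stratified at 50% within load (exact when ``reps_per_load`` is even)."""
    if reps_per_load < 1:
        raise ValueError("reps_per_load must be >= 1")
    if n_units <= max(cfg.loads):
        raise ValueError("lexicon too small for the largest load plus a lure")
    specs = []
    for load in cfg.loads:
        n_match = reps_per_load // 2 + (reps_per_load % 2 and rng.integers(2))
        flags = np.zeros(reps_per_load, dtype=bool)
        flags[:n_match] = True
        rng.shuffle(flags)
        for is_match in flags:
            ids = rng.choice(n_units, size=load, replace=False)
            if is_match:
                target = int(ids[rng.integers(load)])
            else:
                lures = np.setdiff1d(np.arange(n_units), ids)
                target = int(lures[rng.integers(lures.size)])
            specs.append(
                WMTrialSpec(
                    load=int(load),
                    word_ids=tuple(int(w) for w in ids),
                    target_id=target,
                    is_match=bool(is_match),
                )
            )
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


class ForagingEnv:
    """16 reward patches of 8 two-armed bandits, engage/forage dynamics.

    The 128 optimal-arm rewards form one even global grid on
    [reward_low, reward_high], dealt to contexts by stratified assignment:
    the grid is split into 8 value strata of 16, and context c takes the
    c-th value of every stratum.  Each context therefore spans nearly the
    whole value range while the 16 context means are distinct, evenly
    spaced, and ordered low to high — so the value of the proposed bandit is
    close to independent of the patch's foraging value, the design property
    that decouples foraging value from choice difficulty.

    The forage option's design value is the mean of the other 7 bandits in
    the context minus the forage cost.
    """

    def __init__(self, cfg: ForagingTaskConfig) -> None:
        self.cfg = cfg
        n = cfg.n_contexts * cfg.n_bandits
        grid = np.linspace(cfg.reward_low, cfg.reward_high, n)
        strata = grid.reshape(cfg.n_bandits, cfg.n_contexts)
        # optimal_arm[c, b]: context c holds the c-th member of stratum b
        arms = strata.T.copy()
        # contract the context means toward the global mean while keeping the
        # within-context composition: context_spread = 1 keeps the raw means,
        # smaller values make patches more similar in quality (means stay
        # distinct and ordered)
        means = arms.mean(axis=1, keepdims=True)
        arms -= (means - grid.mean()) * (1.0 - cfg.context_spread)
        self.optimal_arm = arms
        self.suboptimal_arm = self.optimal_arm - cfg.arm_margin
        means = self.context_means
        if np.unique(np.round(means, 12)).size != cfg.n_contexts:
            raise ValueError("context means must be distinct")

    @property
    def n_cues(self) -> int:
        return self.cfg.n_contexts * self.cfg.n_bandits

    @property
    def context_means(self) -> np.ndarray:
        return self.optimal_arm.mean(axis=1)

    def forage_value(self, context: int, bandit: int) -> float:
        """Design value of foraging at this cue: mean of the other bandits'
        optimal arms minus the forage cost."""
        vals = self.optimal_arm[context]
        other = (vals.sum() - vals[bandit]) / (vals.size - 1)
        return float(other - self.cfg.forage_cost)

    def engage_value(self, context: int, bandit: int) -> float:
        """Design value of engaging: the proposed bandit's optimal arm."""
        return float(self.optimal_arm[context, bandit])

    def choice_difficulty(self, context: int, bandit: int) -> float:
        """Similarity in value of the two options (0 = indifference point,
        more negative = easier choice)."""
        return -abs(self.engage_value(context, bandit) - self.forage_value(context, bandit))

    def arm_rewards(self, context: int, bandit: int) -> np.ndarray:
        return np.array(
            [self.optimal_arm[context, bandit], self.suboptimal_arm[context, bandit]]
        )

    def redraw_bandit(self, context: int, bandit: int, rng: np.random.Generator) -> int:
        """Forage transition: a different bandit, uniform over the other 7."""
        b = int(rng.integers(self.cfg.n_bandits - 1))
        return b + 1 if b >= bandit else b

    def generate_session_cues(
        self, n_blocks: int, rng: np.random.Generator
    ) -> list[tuple[int, int]]:
        """Initial compound cues: every (context, bandit) twice per block,
        shuffled within block."""
        cues = [
            (c, b)
            for c in range(self.cfg.n_contexts)
            for b in range(self.cfg.n_bandits)
        ]
        session = []
        for _ in range(n_blocks):
            block = cues * 2
            order = rng.permutation(len(block))
            session.extend(block[i] for i in order)
        return session
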