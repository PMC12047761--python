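"""Session runners: pretraining plus the per-trial agent-environment loops.

Each runner simulates one participant end to end and returns a trial-record
table (one row per trial) that downstream analysis treats as the sole source
of truth.  A participant is fully determined by (config, seed): the runner
draws every random number from a single seeded generator.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import ddm as ddm_mod
from .agent import BoostState, KalmanTable, compute_neuromodulation, surprise
from .config import ExperimentConfig
from .envs import (
    ForagingEnv,
    generate_speeded_trials,
    generate_wm_trials,
    reward_devaluation,
    speeded_stimulus_values,
)
from .wm import calibrate_criterion, run_wm_trial_evidence

__all__ = [
    "pretrain_values",
    "run_speeded_session",
    "run_wm_session",
    "run_foraging_session",
    "SPEEDED_COLUMNS",
    "WM_COLUMNS",
    "FORAGING_COLUMNS",
]

log = logging.getLogger(__name__)

SPEEDED_COLUMNS = [
    "task", "participant", "seed", "trial", "left_reward", "right_reward",
    "value_difference", "trial_total_reward", "boost", "lc", "dv",
    "value_regressor", "surprise_regressor", "outcome_surprise", "choice",
    "rt_cycles", "timed_out", "correct", "reward", "net_value",
]

WM_COLUMNS = [
    "task", "participant", "seed", "trial", "load", "is_match", "decision",
    "correct", "boost", "lc", "evidence", "value_regressor",
    "surprise_regressor", "reward", "net_value",
]

FORAGING_COLUMNS = [
    "task", "participant", "seed", "trial", "context", "bandit",
    "engage_value", "forage_value", "choice_difficulty", "boost", "lc", "dv",
    "value_regressor", "surprise_regressor", "choice", "rt_cycles",
    "timed_out", "n_forages", "reward", "net_value",
]


def pretrain_values(
    table: KalmanTable,
    targets: np.ndarray,
    n_obs: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    tolerance: float = 0.2,
) -> KalmanTable:
    """Train a bank of value filters toward stationary targets.

    Feeds each filter ``n_obs`` observations of its target (optionally
    noisy).  Logs a warning with residuals if any estimate ends further than
    ``tolerance`` from its target.
    """
    targets = np.asarray(targets, dtype=float)
    idx = np.arange(len(table))
    for _ in range(n_obs):
        obs = targets if noise_sd == 0 else targets + noise_sd * rng.standard_normal(targets.shape)
        table.update(idx, obs)
    resid = np.abs(table.means - targets)
    if np.any(resid > tolerance):
        log.warning(
            "pretraining did not converge within %.3g: max residual %.3g",
            tolerance, float(resid.max()),
        )
    return table


# ---------------------------------------------------------------------------
# speeded decision-making task
# ---------------------------------------------------------------------------

def run_speeded_session(
    cfg: ExperimentConfig, participant: int, seed: int
) -> pd.DataFrame:
    """One simulated participant of the speeded decision-making task.

    Per trial: boost is selected from the trial-type condition, LC shrinks
    the diffusion boundary, the learned option-value difference sets the
    drift, and the chosen option's reward — linearly devalued by reaction
    time, zero on timeout — feeds back into both the option values and the
    boost q-values (net of boost cost).
    """
    rng = np.random.default_rng(seed)
    task = cfg.speeded
    agent_cfg = cfg.agent
    ddm_cfg = cfg.ddm

    stim_values = speeded_stimulus_values(task)
    values = KalmanTable(
        n=stim_values.size,
        prior_mean=agent_cfg.value_prior_mean,
        prior_var=agent_cfg.value_prior_var,
        obs_noise=agent_cfg.value_obs_noise,
        process_noise=agent_cfg.process_noise,
    )
    pretrain_values(values, stim_values, task.pretrain_obs, rng)

    boost_state = BoostState(agent_cfg)
    levels = np.arange(task.reward_min, task.reward_max + 1)
    for lv in levels:
        for rv in levels:
            boost_state.register_state((int(lv), int(rv)))

    trials = generate_speeded_trials(task.reps_per_type, task, rng)
    session_mean_total = float(np.mean([t.total_reward for t in trials]))

    rows = []
    for t_idx, trial in enumerate(trials):
        state_id = (trial.left_reward, trial.right_reward)
        level, level_idx = boost_state.select_boost(state_id, rng)
        signals = compute_neuromodulation(level, agent_cfg)
        value_regressor = boost_state.state_value(state_id)

        dv = float(values.means[trial.left_stim] - values.means[trial.right_stim])
        drift = ddm_mod.drift_from_dv(dv, ddm_cfg)
        boundary = ddm_mod.boundary_from_lc(signals.lc, ddm_cfg)
        bias = ddm_mod.bias_from_lc(signals.lc, boundary, ddm_cfg)
        out = ddm_mod.run_ddm(drift, boundary, bias, ddm_cfg, rng)

        best = max(trial.left_reward, trial.right_reward)
        if out.timed_out:
            reward = 0.0
            correct = False
            outcome_pe = np.nan
        else:
            chose_left = out.choice == 1  # upper boundary = left option
            stim = trial.left_stim if chose_left else trial.right_stim
            raw = trial.left_reward if chose_left else trial.right_reward
            correct = raw == best
            reward = reward_devaluation(raw, out.rt_cycles, ddm_cfg.max_cycles)
            outcome_pe = surprise(float(values.means[stim]), reward)
            values.update(stim, reward, vta=signals.vta)

        net = reward - boost_state.cost(level)
        boost_state.update(state_id, level_idx, net)

        rows.append((
            "speeded", participant, seed, t_idx, trial.left_reward,
            trial.right_reward, trial.value_difference, trial.total_reward,
            level, signals.lc, dv, value_regressor,
            abs(trial.total_reward - session_mean_total), outcome_pe,
            out.choice, out.rt_cycles, out.timed_out, correct, reward, net,
        ))
    return pd.DataFrame(rows, columns=SPEEDED_COLUMNS)


# ---------------------------------------------------------------------------
# verbal working-memory task
# ---------------------------------------------------------------------------

def _wm_agent_config(cfg: ExperimentConfig):
    """Agent priors rescaled to the WM task's 0/1 reward range."""
    return dataclasses.replace(
        cfg.agent,
        q_prior_mean=1.0,  # optimistic: the largest attainable reward
        q_prior_var=1.0,
        q_obs_noise=0.15,
        value_prior_mean=0.5,
        value_prior_var=1.0,
        value_obs_noise=0.2,
        boost_temperature=cfg.agent.boost_temperature * 0.1,
    )


def run_wm_session(
    cfg: ExperimentConfig, participant: int, seed: int
) -> pd.DataFrame:
    """One simulated participant of the verbal WM task.

    Boost is selected from the load cue; LC raises the network's output
    gain, improving retention.  Correct/incorrect feedback is delivered as
    reward 1/0 and drives both boost learning (net of cost) and a per-load
    outcome expectation used for the surprise and value regressors.
    """
    rng = np.random.default_rng(seed)
    task = cfg.wm_task
    # individual differences: each simulated participant has their own WM
    # capacity (inhibition strength) and attentional lapse rate
    net_cfg = dataclasses.replace(
        cfg.wm,
        inhibition_weight=max(
            0.0, rng.normal(cfg.wm.inhibition_weight, cfg.wm.inhibition_weight_sd)
        ),
        encoding_lapse=float(
            np.clip(rng.normal(cfg.wm.encoding_lapse, cfg.wm.encoding_lapse_sd), 0.0, 0.9)
        ),
    )
    agent_cfg = _wm_agent_config(cfg)

    criterion = calibrate_criterion(
        net_cfg, task.loads, rng, n_trials=task.calibration_trials
    )

    boost_state = BoostState(agent_cfg, cost_rate=task.cost_rate)
    loads = [int(l) for l in task.loads]
    for load in loads:
        boost_state.register_state(load)
    outcome_values = KalmanTable(
        n=len(loads),
        prior_mean=agent_cfg.value_prior_mean,
        prior_var=agent_cfg.value_prior_var,
        obs_noise=agent_cfg.value_obs_noise,
    )
    load_index = {load: i for i, load in enumerate(loads)}

    def play(spec, t_idx, rows):
        level, level_idx = boost_state.select_boost(spec.load, rng)
        signals = compute_neuromodulation(level, agent_cfg)

        evidence = run_wm_trial_evidence(spec, signals.lc, net_cfg, rng)
        decision = evidence > criterion
        correct = decision == spec.is_match
        reward = task.reward_correct if correct else task.reward_incorrect

        li = load_index[spec.load]
        expected = float(outcome_values.means[li])
        pe = surprise(expected, reward)
        # value expectation regressor: mean of the action-module outcome
        # prediction and the boost module's expected outcome (gross of the
        # control cost, which is accounted for in the boost signal itself)
        value_regressor = 0.5 * (expected + boost_state.expected_outcome(spec.load))
        outcome_values.update(li, reward)

        net = reward - boost_state.cost(level)
        boost_state.update(spec.load, level_idx, net)

        if rows is not None:
            rows.append((
                "wm", participant, seed, t_idx, spec.load, spec.is_match,
                bool(decision), bool(correct), level, signals.lc, evidence,
                value_regressor, pe, reward, net,
            ))

    # unrecorded practice: the boost policy and outcome expectations reach
    # their task-adapted state before the session proper, as they would in
    # participants trained on the task before scanning
    if task.practice_reps_per_load > 0:
        for spec in generate_wm_trials(task.practice_reps_per_load, task,
                                       net_cfg.n_units, rng):
            play(spec, -1, None)

    specs = generate_wm_trials(task.reps_per_load, task, net_cfg.n_units, rng)
    rows: list = []
    for t_idx, spec in enumerate(specs):
        play(spec, t_idx, rows)
    return pd.DataFrame(rows, columns=WM_COLUMNS)


# ---------------------------------------------------------------------------
# foraging task
# ---------------------------------------------------------------------------

def _pretrain_foraging(
    env: ForagingEnv,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
):
    """Pretraining: arm values, engage values and forage values per cue."""
    agent_cfg = cfg.agent
    task = cfg.foraging
    n = env.n_cues

    def make_table(size: int) -> KalmanTable:
        return KalmanTable(
            n=size,
            prior_mean=agent_cfg.value_prior_mean,
            prior_var=agent_cfg.value_prior_var,
            obs_noise=agent_cfg.value_obs_noise,
            process_noise=agent_cfg.process_noise,
        )

    arm_values = make_table(2 * n)  # [cue * 2 + arm]
    opt = env.optimal_arm.ravel()
    sub = env.suboptimal_arm.ravel()
    pretrain_values(arm_values, np.column_stack([opt, sub]).ravel(), task.pretrain_obs, rng)

    # engage value: outcome of playing the proposed bandit with the learned
    # (near-greedy) arm policy; with a wide margin this converges to the
    # optimal arm's reward
    engage_values = make_table(n)
    for _ in range(task.pretrain_obs):
        pick_sub = rng.random(n) < _suboptimal_arm_prob(arm_values, agent_cfg)
        outcome = np.where(pick_sub, sub, opt)
        engage_values.update(np.arange(n), outcome)

    # forage value: one-step lookahead sample — pay the forage cost, then
    # value the redrawn bandit by its learned engage value.  In expectation
    # this is the context mean excluding the current bandit, minus the cost.
    forage_values = make_table(n)
    nb = task.n_bandits
    for _ in range(task.pretrain_obs):
        for c in range(task.n_contexts):
            base = c * nb
            for b in range(nb):
                alt = env.redraw_bandit(c, b, rng)
                target = -task.forage_cost + float(engage_values.means[base + alt])
                forage_values.update(base + b, target)
    return arm_values, engage_values, forage_values


def _suboptimal_arm_prob(arm_values: KalmanTable, agent_cfg) -> np.ndarray:
    means = arm_values.means.reshape(-1, 2)
    z = (means[:, 1] - means[:, 0]) / agent_cfg.action_temperature
    return 1.0 / (1.0 + np.exp(-z))


def run_foraging_session(
    cfg: ExperimentConfig, participant: int, seed: int
) -> pd.DataFrame:
    """One simulated participant of the foraging task.

    Each trial proposes a (context, bandit) compound cue.  Boost is selected
    at every proposal from that cue; the engage/forage decision runs through
    the diffusion module with the learned engage-forage value difference as
    drift, an LC-shrunk boundary, and an LC-discounted engage bias.  Engaging
    plays the cued two-armed bandit; foraging pays a waiting cost and redraws
    a different bandit from the same context (at most 20 consecutive
    forages); exceeding the 2000-cycle deadline aborts the trial unrewarded.

    One record is emitted per trial, carrying the *initial* proposal's cue,
    boost and value signals (the quantities entering the analysis), plus the
    trial's final outcome.
    """
    rng = np.random.default_rng(seed)
    task = cfg.foraging
    agent_cfg = cfg.agent
    ddm_cfg = cfg.foraging_ddm

    env = ForagingEnv(task)
    arm_values, engage_values, forage_values = _pretrain_foraging(env, cfg, rng)

    boost_state = BoostState(agent_cfg)
    for c in range(task.n_contexts):
        for b in range(task.n_bandits):
            boost_state.register_state((c, b))

    cues = env.generate_session_cues(task.n_blocks, rng)
    nb = task.n_bandits
    rows = []
    for t_idx, (c0, b0) in enumerate(cues):
        c, b = c0, b0
        consec_forages = 0
        total_costs = 0.0
        final_reward = 0.0
        timed_out = False
        first = None

        while True:
            state_id = (c, b)
            cue = c * nb + b
            level, level_idx = boost_state.select_boost(state_id, rng)
            signals = compute_neuromodulation(level, agent_cfg)
            dv = float(engage_values.means[cue] - forage_values.means[cue])
            drift = ddm_mod.drift_from_dv(dv, ddm_cfg)
            boundary = ddm_mod.boundary_from_lc(signals.lc, ddm_cfg)
            bias = ddm_mod.bias_from_lc(signals.lc, boundary, ddm_cfg)
            out = ddm_mod.run_ddm(drift, boundary, bias, ddm_cfg, rng)

            if first is None:
                # cue-onset quantities entering the analysis, captured before
                # any learning update from this trial
                first = (
                    state_id, level, signals.lc, dv, out,
                    boost_state.state_value(state_id),
                )

            if out.timed_out:
                # aborted trial: the proposal earned nothing
                boost_state.update(state_id, level_idx, -boost_state.cost(level))
                timed_out = True
                break
            if out.choice == 1:  # upper boundary = engage
                pick_sub = rng.random() < float(
                    _suboptimal_arm_prob(arm_values, agent_cfg)[cue]
                )
                arm = 1 if pick_sub else 0
                final_reward = float(env.arm_rewards(c, b)[arm])
                arm_values.update(cue * 2 + arm, final_reward)
                engage_values.update(cue, final_reward)
                boost_state.update(
                    state_id, level_idx, final_reward - boost_state.cost(level)
                )
                break
            # forage: pay the waiting cost, redraw a different bandit
            consec_forages += 1
            total_costs += task.forage_cost
            forage_cue = cue
            if consec_forages >= task.max_consecutive_forages:
                forage_values.update(forage_cue, -task.forage_cost)
                boost_state.update(
                    state_id, level_idx,
                    -task.forage_cost - boost_state.cost(level),
                )
                break
            b = env.redraw_bandit(c, b, rng)
            # one-step bootstrapped continuation: pay the waiting cost, value
            # the redrawn cue by the better of its learned option values
            next_cue = c * nb + b
            continuation = -task.forage_cost + max(
                float(engage_values.means[next_cue]),
                float(forage_values.means[next_cue]),
            )
            forage_values.update(
                forage_cue,
                -task.forage_cost + float(engage_values.means[next_cue]),
            )
            boost_state.update(
                state_id, level_idx, continuation - boost_state.cost(level)
            )

        (state_id, level, lc, dv, out0, value_regressor) = first
        c_i, b_i = state_id
        net_first = final_reward - total_costs - boost_state.cost(level)
        rows.append((
            "foraging", participant, seed, t_idx, c_i, b_i,
            env.engage_value(c_i, b_i), env.forage_value(c_i, b_i),
            env.choice_difficulty(c_i, b_i), level, lc, dv, value_regressor,
            abs(net_first - value_regressor), out0.choice, out0.rt_cycles,
            timed_out, consec_forages, final_reward,
            final_reward - total_costs - boost_state.cost(level),
        ))
    return pd.DataFrame(rows, columns=FORAGING_COLUMNS)
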