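"""Verbal working-memory module: a dual-layer competitive recurrent network.

The input (phonological) layer has one unit per word in the lexicon; units
for the presented words are clamped on for the whole retention delay.  The
output (articulatory) layer integrates the clamped input through a recurrent
weight whose effective strength is multiplied by a gain set from LC output,
leaks, and receives saturating lateral inhibition from the other output
units.  More concurrently active units means more inhibition, so retention
precision falls with load; raising the gain (cognitive control) restores it.

The match/non-match decision reads out the probed unit's end-of-delay
activation against a criterion calibrated once on a held-out block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CRNNConfig

__all__ = [
    "WMTrialSpec",
    "NetState",
    "encode_words",
    "run_retention",
    "probe_decision",
    "output_gain",
    "run_wm_trial_evidence",
    "calibrate_criterion",
]


@dataclass(frozen=True)
class WMTrialSpec:
    """One WM trial: the presented set, the probe, and the match flag."""

    load: int
    word_ids: tuple
    target_id: int
    is_match: bool

    def __post_init__(self) -> None:
        if len(set(self.word_ids)) != len(self.word_ids):
            raise ValueError("word_ids must be distinct")
        if len(self.word_ids) != self.load:
            raise ValueError("|word_ids| must equal load")
        if self.is_match != (self.target_id in self.word_ids):
            raise ValueError("is_match inconsistent with word_ids/target_id")


@dataclass
class NetState:
    """Activations of both layers (input clamped, output dynamic)."""

    input: np.ndarray
    output: np.ndarray

    def copy(self) -> "NetState":
        return NetState(self.input.copy(), self.output.copy())


def encode_words(
    spec: WMTrialSpec,
    config: CRNNConfig,
    rng: np.random.Generator | None = None,
) -> NetState:
    """Activate the presented words in both layers (phonological trace plus
    an initial articulatory activation); all other units start at baseline.

    Each presented word independently fails to be encoded at all with
    probability ``encoding_lapse`` (an attentional lapse at presentation);
    such words can never be recovered later, whatever the gain.  Pass
    ``rng=None`` for lapse-free deterministic encoding.
    """
    ids = np.asarray(spec.word_ids, dtype=int)
    if ids.size != np.unique(ids).size:
        raise ValueError("duplicate word ids")
    if ids.min() < 0 or ids.max() >= config.n_units:
        raise ValueError("word id outside the lexicon")
    x = np.zeros(config.n_units)
    x[ids] = config.encoding_activation
    if rng is not None and config.encoding_lapse > 0:
        lapsed = rng.random(ids.size) < config.encoding_lapse
        x[ids[lapsed]] = 0.0
    # encoded words start in the active (just-articulated) state
    return NetState(input=x, output=x.copy())


def output_gain(lc: float, config: CRNNConfig) -> float:
    """Output-layer gain as a function of LC output (linear, non-negative)."""
    return max(0.0, config.gain_base + config.gain_lc_coeff * lc)


def run_retention(
    state: NetState,
    lc: float,
    config: CRNNConfig,
    rng: np.random.Generator,
) -> NetState:
    """Iterate the retention dynamics for the configured delay.

    Per step, for output unit j with activation y_j and (decaying)
    phonological input x_j:

        y_j <- clip( y_j + ( -leak * y_j
                             + gain * ( w_rec * x_j + w_self * sat(y_j) )
                             - w_inh * sum_{k != j} sat(y_k) )
                     + noise,  0, activation_max )
        x_j <- (1 - input_decay) * x_j

    with sat(y) = (y - theta)+ / ((y - theta)+ + h) a thresholded,
    saturating transfer of active units.  The phonological trace fades, so a
    word survives the delay only if its output unit reaches the self-
    sustaining (articulatory rehearsal) attractor; the threshold keeps
    baseline noise from igniting spurious attractors; and the shared
    lateral-inhibition pool limits how many units can rehearse at once.
    Because the self-excitation is gain-modulated, that capacity grows with
    LC output — which is exactly how cognitive control pays for a longer
    list.
    """
    g = output_gain(lc, config)
    x = state.input.copy()
    y = state.output.copy()
    h = config.activity_half_sat
    theta = config.activity_threshold
    for _ in range(config.delay_steps):
        above = np.maximum(y - theta, 0.0)
        sat = above / (above + h)
        lateral = config.inhibition_weight * (sat.sum() - sat)
        dy = (
            -config.leak * y
            + config.baseline_drive
            + g * (config.recurrent_weight * x + config.self_weight * sat)
            - lateral
        )
        y = y + dy + config.noise_sd * rng.standard_normal(y.size)
        np.clip(y, 0.0, config.activation_max, out=y)
        x *= 1.0 - config.input_decay
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("activation overflow in retention dynamics")
    return NetState(input=x, output=y)


def probe_decision(
    state: NetState, target_id: int, criterion: float
) -> tuple[bool, float]:
    """Match decision from the probed unit's end-of-delay activation.

    The readout is the one-hot linear combination of the output layer
    referenced to the probed unit; the decision is 'match' iff that evidence
    exceeds the criterion.
    """
    evidence = float(state.output[target_id])
    return evidence > criterion, evidence


def run_wm_trial_evidence(
    spec: WMTrialSpec,
    lc: float,
    config: CRNNConfig,
    rng: np.random.Generator,
) -> float:
    """Encode, retain, and return the probe evidence for one trial."""
    state = encode_words(spec, config, rng)
    state = run_retention(state, lc, config, rng)
    return float(state.output[spec.target_id])


def calibrate_criterion(
    config: CRNNConfig,
    loads,
    rng: np.random.Generator,
    n_trials: int = 400,
    lc: float = 0.5,
) -> float:
    """Fix the match criterion once, on a held-out calibration block.

    Simulates probe evidence for match and non-match trials at a mid-range
    LC across all loads and returns the threshold that maximizes accuracy on
    that block.  The criterion is then frozen for the whole experiment.
    """
    loads = list(loads)
    match_ev, nonmatch_ev = [], []
    for i in range(n_trials):
        load = loads[i % len(loads)]
        ids = rng.choice(config.n_units, size=load, replace=False)
        is_match = i % 2 == 0
        if is_match:
            target = int(ids[rng.integers(load)])
        else:
            others = np.setdiff1d(np.arange(config.n_units), ids)
            target = int(others[rng.integers(others.size)])
        spec = WMTrialSpec(
            load=load, word_ids=tuple(int(w) for w in ids), target_id=target,
            is_match=is_match,
        )
        ev = run_wm_trial_evidence(spec, lc, config, rng)
        (match_ev if is_match else nonmatch_ev).append(ev)
    match_ev = np.sort(match_ev)
    nonmatch_ev = np.asarray(nonmatch_ev)
    # scan a fixed threshold grid; the floor keeps the criterion above the
    # baseline noise band so lure units cannot trigger spurious matches
    candidates = np.linspace(0.15, 0.9, 31)
    best_c, best_acc = float(candidates[0]), -1.0
    for c in candidates:
        acc = 0.5 * np.mean(match_ev > c) + 0.5 * np.mean(nonmatch_ev <= c)
        if acc > best_acc:
            best_acc, best_c = float(acc), float(c)
    return best_c
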