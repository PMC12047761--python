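"""Configuration objects for the RML agent, task modules and analysis.

Every tunable parameter of the model lives here, with defaults.  The RML
literature treats these as fixed model constants; we expose all of them so a
run is fully determined by (config, seed) and can be reproduced from its
serialized manifest alone.

Configs are plain dataclasses.  :func:`load_config` reads a YAML/JSON file
with sections ``agent`` / ``ddm`` / ``wm`` / ``task`` / ``analysis`` and fills
defaults; unknown keys raise :class:`ConfigError` naming the key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "AgentConfig",
    "DDMConfig",
    "CRNNConfig",
    "SpeededTaskConfig",
    "WMTaskConfig",
    "ForagingTaskConfig",
    "AnalysisConfig",
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "dump_config",
]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


@dataclass
class AgentConfig:
    """Task-independent RML parameters.

    Boost is a discrete control intensity on an ordered grid.  Its learned
    action values (and the option values of the action module) are tracked by
    scalar Kalman filters.  LC and VTA outputs are affine-then-clipped maps of
    the selected boost level; with ``vta_coeff = 0`` the VTA output is the
    neutral 1.0 and reward signals are passed through unscaled.
    """

    n_boost_levels: int = 10
    boost_min: float = 1.0
    boost_max: float = 10.0
    boost_temperature: float = 0.2  # softmax temperature for boost selection
    boost_generalization: float = 2.5  # kernel width (in levels) for q-value updates
    action_temperature: float = 0.25  # softmax temperature for motor actions
    cost_rate: float = 0.19  # reward units per boost unit (linear cost)
    q_prior_mean: float = 7.0  # optimistic prior for boost q-values (max reward)
    q_prior_var: float = 25.0
    q_obs_noise: float = 1.0  # assumed outcome variance in the boost Kalman filters
    value_prior_mean: float = 4.5
    value_prior_var: float = 25.0
    value_obs_noise: float = 1.0  # assumed outcome variance in the action-value filters
    process_noise: float = 0.0  # additive Kalman drift variance (0: stationary tasks)
    lc_min: float = 0.0
    lc_max: float = 1.0
    vta_base: float = 1.0  # 1.0 = no scaling of outcomes
    vta_coeff: float = 0.0
    vta_min: float = 0.0
    vta_max: float = 2.0

    def __post_init__(self) -> None:
        if self.n_boost_levels < 1:
            raise ConfigError("n_boost_levels must be >= 1")
        if self.boost_max < self.boost_min:
            raise ConfigError("boost_max must be >= boost_min")
        for key in ("boost_temperature", "action_temperature"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be strictly positive")
        for key in ("cost_rate", "q_prior_var", "process_noise", "boost_generalization"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        for key in ("q_obs_noise", "value_obs_noise"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be strictly positive")
        if self.lc_max < self.lc_min:
            raise ConfigError("lc_max must be >= lc_min")


@dataclass
class DDMConfig:
    """Discrete-time diffusion (one Euler step per 'DDM cycle').

    ``base_boundary`` is the half-separation at minimum LC output; LC shrinks
    the boundary linearly down to ``boundary_floor``.  ``bias0`` is the
    baseline starting point toward the upper boundary (the 'engage' side in
    the foraging task; 0 in the speeded task), discounted toward 0 by LC.
    """

    base_boundary: float = 160.0
    boundary_lc_slope: float = 0.85  # fractional shrink at maximum LC
    boundary_floor: float = 10.0
    noise_sd: float = 1.0  # per-cycle diffusion noise
    drift_scale: float = 0.013  # evidence per cycle per reward-unit of dv
    max_cycles: int = 14000  # response deadline, in cycles
    bias0: float = 0.0
    bias_lc_discount: float = 1.0  # fractional bias reduction at maximum LC

    def __post_init__(self) -> None:
        if self.base_boundary <= 0 or self.boundary_floor <= 0:
            raise ConfigError("boundaries must be strictly positive")
        if self.boundary_floor > self.base_boundary:
            raise ConfigError("boundary_floor must not exceed base_boundary")
        if not 0 <= self.boundary_lc_slope <= 1:
            raise ConfigError("boundary_lc_slope must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be strictly positive")
        if self.max_cycles < 1:
            raise ConfigError("max_cycles must be >= 1")
        if abs(self.bias0) >= self.boundary_floor:
            raise ConfigError("|bias0| must stay below the boundary floor")
        if not 0 <= self.bias_lc_discount <= 1:
            raise ConfigError("bias_lc_discount must be in [0, 1]")


@dataclass
class CRNNConfig:
    """Dual-layer competitive recurrent network for verbal working memory.

    The input (phonological) layer holds one unit per word; its trace decays
    during the delay.  Output (articulatory) units carry gain-modulated,
    thresholded self-excitation (gain = ``gain_base + gain_lc_coeff * lc``),
    leak, a small spontaneous baseline drive, and a shared saturating
    lateral-inhibition pool.  A word survives the delay only in the
    self-sustaining rehearsal attractor; the inhibition pool caps how many
    units can rehearse at once, and that capacity grows with the LC-driven
    gain — so control buys list capacity at the price of boost cost.
    Encoding lapses and the baseline drive set the irreducible error floor;
    per-participant jitter of capacity and lapse rate models individual
    differences.
    """

    n_units: int = 16  # lexicon size; must exceed the largest load
    recurrent_weight: float = 0.2
    self_weight: float = 0.45  # output-unit self-excitation (attractor term)
    input_decay: float = 0.15  # per-step fading of the phonological trace
    inhibition_weight: float = 0.045
    inhibition_weight_sd: float = 0.004  # between-participant capacity spread
    activity_threshold: float = 0.3  # activity below this neither competes nor self-sustains
    activity_half_sat: float = 0.05  # half-saturation of the active-state transfer
    leak: float = 0.2
    baseline_drive: float = 0.032  # spontaneous drive to every output unit
    gain_base: float = 0.45
    gain_lc_coeff: float = 1.2
    delay_steps: int = 50  # retention delay (10 s at 0.2 s per step)
    noise_sd: float = 0.06  # per-step activation noise
    activation_max: float = 1.0
    encoding_activation: float = 1.0
    encoding_lapse: float = 0.22  # P(a presented word is never encoded)
    encoding_lapse_sd: float = 0.04  # between-participant lapse spread

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigError("n_units must be >= 2")
        if self.inhibition_weight < 0:
            raise ConfigError("inhibition_weight must be >= 0")
        if self.leak <= 0 or self.leak > 1:
            raise ConfigError("leak must be in (0, 1]")
        if not 0 <= self.input_decay <= 1:
            raise ConfigError("input_decay must be in [0, 1]")
        if self.delay_steps < 1:
            raise ConfigError("delay_steps must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.encoding_lapse < 1:
            raise ConfigError("encoding_lapse must be in [0, 1)")


@dataclass
class SpeededTaskConfig:
    """Speeded decision-making design (two options, rewards 2..7)."""

    reward_min: int = 2
    reward_max: int = 7
    reps_per_type: int = 54  # 36 trial types -> 1944 trials
    n_participants: int = 200
    pretrain_obs: int = 30  # observations per stimulus during value pretraining

    def __post_init__(self) -> None:
        if self.reward_max <= self.reward_min:
            raise ConfigError("reward_max must exceed reward_min")
        if self.reps_per_type < 1 or self.n_participants < 1:
            raise ConfigError("counts must be >= 1")


@dataclass
class WMTaskConfig:
    """Verbal working-memory design (loads 1/4/6/8, 50% match probes)."""

    loads: tuple = (1, 4, 6, 8)
    reps_per_load: int = 90  # -> 360 trials
    n_participants: int = 15
    reward_correct: float = 1.0
    reward_incorrect: float = 0.0
    cost_rate: float = 0.012  # boost cost per level, in 0/1 reward units
    calibration_trials: int = 400  # held-out block used once to fix the criterion
    practice_reps_per_load: int = 90  # unrecorded practice before the session

    def __post_init__(self) -> None:
        if len(set(self.loads)) != len(self.loads):
            raise ConfigError("loads must be distinct")
        if self.reps_per_load < 1 or self.n_participants < 1:
            raise ConfigError("counts must be >= 1")


@dataclass
class ForagingTaskConfig:
    """Foraging design: 16 contexts x 8 two-armed bandits, engage/forage."""

    n_contexts: int = 16
    n_bandits: int = 8
    reward_low: float = 2.0
    reward_high: float = 7.0
    arm_margin: float = 2.0  # suboptimal arm reward = optimal - margin
    context_spread: float = 0.75  # scale of context-mean differences
    forage_cost: float = 0.1  # waiting-state cost per forage
    max_consecutive_forages: int = 20
    n_blocks: int = 18  # each block shows all 128 cues twice -> 256 trials
    n_participants: int = 40
    pretrain_obs: int = 25

    def __post_init__(self) -> None:
        if self.n_contexts < 1 or self.n_bandits < 2:
            raise ConfigError("need >= 1 context and >= 2 bandits per context")
        if self.reward_high <= self.reward_low:
            raise ConfigError("reward_high must exceed reward_low")
        if self.max_consecutive_forages < 1:
            raise ConfigError("max_consecutive_forages must be >= 1")


@dataclass
class AnalysisConfig:
    """Binning and model-comparison settings for the regressor analysis."""

    foraging_value_bins: int = 8
    foraging_difficulty_bins: int = 8
    use_aicc: bool = False  # small-sample corrected AIC toggle
    poly_degrees: tuple = (1, 2, 4)

    def __post_init__(self) -> None:
        if self.foraging_value_bins < 6 or self.foraging_difficulty_bins < 4:
            raise ConfigError("too few bins to resolve the reported profiles")


# Per-task DDM defaults differ: the foraging task has a shorter deadline, a
# tighter baseline boundary and an engage bias; the speeded task has no bias.
def speeded_ddm_defaults() -> DDMConfig:
    return DDMConfig()


def foraging_ddm_defaults() -> DDMConfig:
    return DDMConfig(
        base_boundary=60.0,
        boundary_lc_slope=0.85,
        boundary_floor=8.0,
        noise_sd=1.0,
        drift_scale=0.05,
        max_cycles=2000,
        bias0=2.0,
        bias_lc_discount=1.0,
    )


@dataclass
class ExperimentConfig:
    """Resolved configuration for one experiment run."""

    agent: AgentConfig = field(default_factory=AgentConfig)
    ddm: DDMConfig = field(default_factory=speeded_ddm_defaults)
    foraging_ddm: DDMConfig = field(default_factory=foraging_ddm_defaults)
    wm: CRNNConfig = field(default_factory=CRNNConfig)
    speeded: SpeededTaskConfig = field(default_factory=SpeededTaskConfig)
    wm_task: WMTaskConfig = field(default_factory=WMTaskConfig)
    foraging: ForagingTaskConfig = field(default_factory=ForagingTaskConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    base_seed: int = 0


_SECTIONS = {
    "agent": AgentConfig,
    "ddm": DDMConfig,
    "foraging_ddm": DDMConfig,
    "wm": CRNNConfig,
    "speeded": SpeededTaskConfig,
    "wm_task": WMTaskConfig,
    "foraging": ForagingTaskConfig,
    "analysis": AnalysisConfig,
}


def _build_section(section: str, data: Mapping[str, Any]) -> Any:
    cls = _SECTIONS[section]
    default = ExperimentConfig.__dataclass_fields__[section].default_factory()
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {', '.join(unknown)}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return dataclasses.replace(default, **coerced)


def config_from_dict(data: Mapping[str, Any] | None) -> ExperimentConfig:
    """Build a fully resolved :class:`ExperimentConfig` from a nested mapping."""
    data = dict(data or {})
    base_seed = data.pop("base_seed", 0)
    if not isinstance(base_seed, int):
        raise ConfigError("base_seed must be an integer")
    unknown = sorted(set(data) - set(_SECTIONS))
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(unknown)}")
    kwargs = {name: _build_section(name, data.get(name, {}) or {}) for name in _SECTIONS}
    return ExperimentConfig(base_seed=base_seed, **kwargs)


def config_to_dict(cfg: ExperimentConfig) -> dict:
    out = {name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS}
    for section in out.values():
        for k, v in section.items():
            if isinstance(v, tuple):
                section[k] = list(v)
    out["base_seed"] = cfg.base_seed
    return out


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Load a YAML (or JSON) config file; ``None`` or empty file -> defaults."""
    if path is None:
        return ExperimentConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    return config_from_dict(data)


def dump_config(cfg: ExperimentConfig, path: str | Path | None = None) -> str:
    """Serialize the fully resolved config to YAML; optionally write it."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def dump_config_json(cfg: ExperimentConfig) -> str:
    return json.dumps(config_to_dict(cfg), indent=2, sort_keys=True)
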