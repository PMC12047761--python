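"""Task-independent core of the Reinforcement Meta-Learner (RML).

The agent tracks expected net value (reward minus control cost) with scalar
Kalman filters, and *meta-learns* how much cognitive control ("boost") to
exert: boost is a discrete intensity selected by softmax over Kalman-learned
action values, carries a linear intrinsic cost, and drives two simulated
neuromodulatory outputs — LC (gain/urgency: shrinks decision boundaries,
raises network gain) and VTA (reward-signal scaling, neutral at 1).

Two value stores mirror the two medial-prefrontal modules of the model: an
action module holding option values (whose difference is ``dv``), and a boost
module holding one value estimate per (condition, boost level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import AgentConfig

__all__ = [
    "ValueEstimate",
    "NeuromodSignals",
    "BoostState",
    "KalmanTable",
    "kalman_update",
    "surprise",
    "trial_type_surprise",
    "boost_cost",
    "compute_neuromodulation",
    "compute_dv",
    "softmax_probs",
]


@dataclass(frozen=True)
class ValueEstimate:
    """A Kalman-tracked expected value: mean, uncertainty, outcome variance.

    ``mean`` is in reward units, ``uncertainty`` (estimation variance) and
    ``observation_noise`` (assumed outcome variance) in reward units squared.
    """

    mean: float
    uncertainty: float
    observation_noise: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if not np.isfinite(self.uncertainty) or self.uncertainty < 0:
            raise ValueError("uncertainty must be finite and non-negative")
        if self.observation_noise < 0:
            raise ValueError("observation_noise must be non-negative")

    @property
    def gain(self) -> float:
        """Kalman gain for the next update."""
        denom = self.uncertainty + self.observation_noise
        return 1.0 if denom == 0 else self.uncertainty / denom


@dataclass(frozen=True)
class NeuromodSignals:
    """LC and VTA scalar outputs for the currently selected boost level."""

    lc: float
    vta: float


def kalman_update(
    estimate: ValueEstimate,
    outcome: float,
    vta: float = 1.0,
    process_noise: float = 0.0,
) -> ValueEstimate:
    """One scalar Kalman update toward a (VTA-scaled) observed outcome.

    mean' = mean + k (vta*outcome - mean), k = u / (u + r)
    u'    = (1 - k) u + process_noise

    The input estimate is not mutated.  ``process_noise`` (drift variance)
    defaults to 0, appropriate for the stationary tasks simulated here; a
    positive value keeps the filter plastic in nonstationary environments.
    """
    if not np.isfinite(outcome):
        raise ValueError("outcome must be finite")
    if not np.isfinite(vta) or vta < 0:
        raise ValueError("vta scaling must be finite and non-negative")
    k = estimate.gain
    mean = estimate.mean + k * (vta * outcome - estimate.mean)
    uncertainty = (1.0 - k) * estimate.uncertainty + process_noise
    return replace(estimate, mean=mean, uncertainty=uncertainty)


def surprise(estimate_mean: float, outcome: float) -> float:
    """Unsigned prediction error |outcome - expectation|."""
    if not (np.isfinite(estimate_mean) and np.isfinite(outcome)):
        raise ValueError("inputs must be finite")
    return abs(outcome - estimate_mean)


def trial_type_surprise(trial_total_reward: float, long_term_mean_reward: float) -> float:
    """Trial-type surprise: |total reward on offer - long-term session mean|.

    Used only as an analysis regressor (mid-cingulate-like surprise signal in
    the speeded task); the long-term mean is computed over the whole session.
    """
    return abs(trial_total_reward - long_term_mean_reward)


def boost_cost(level: float, cost_rate: float) -> float:
    """Intrinsic cost of control: linear in boost with zero intercept."""
    if level < 0:
        raise ValueError("boost level must be non-negative")
    return cost_rate * level


def softmax_probs(values: np.ndarray, temperature: float) -> np.ndarray:
    """Numerically stable softmax of ``values / temperature``."""
    if temperature <= 0:
        raise ValueError("temperature must be strictly positive")
    z = np.asarray(values, dtype=float) / temperature
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


class KalmanTable:
    """A vectorized bank of independent scalar Kalman filters.

    Backs both medial-prefrontal value stores.  The arithmetic is identical
    to :func:`kalman_update` applied elementwise; a property test holds the
    two routes to agreement.
    """

    def __init__(
        self,
        n: int,
        prior_mean: float,
        prior_var: float,
        obs_noise: float,
        process_noise: float = 0.0,
    ) -> None:
        if n < 1:
            raise ValueError("table must hold at least one estimate")
        self.means = np.full(n, float(prior_mean))
        self.uncertainties = np.full(n, float(prior_var))
        self.obs_noise = float(obs_noise)
        self.process_noise = float(process_noise)

    def __len__(self) -> int:
        return self.means.size

    def estimate(self, idx: int) -> ValueEstimate:
        return ValueEstimate(
            mean=float(self.means[idx]),
            uncertainty=float(self.uncertainties[idx]),
            observation_noise=self.obs_noise,
        )

    def update(self, idx, outcome, vta: float = 1.0, obs_weight=1.0) -> None:
        """Update one or several filters toward their observed outcomes.

        ``obs_weight`` in (0, 1] discounts an observation's reliability by
        inflating its assumed noise to ``obs_noise / weight`` (weight 0 skips
        the update); used for generalization across neighboring conditions.
        """
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        outcome = np.broadcast_to(np.asarray(outcome, dtype=float), idx.shape)
        weight = np.broadcast_to(np.asarray(obs_weight, dtype=float), idx.shape)
        if not np.all(np.isfinite(outcome)):
            raise ValueError("outcomes must be finite")
        with np.errstate(divide="ignore"):
            r_eff = np.where(weight > 0, self.obs_noise / np.maximum(weight, 1e-300), np.inf)
        u = self.uncertainties[idx]
        k = np.where(np.isinf(r_eff), 0.0, u / (u + r_eff))
        self.means[idx] = self.means[idx] + k * (vta * outcome - self.means[idx])
        self.uncertainties[idx] = (1.0 - k) * u + self.process_noise


class BoostState:
    """Learned boost policy: q-values per (condition, level), linear cost.

    Conditions (task states visible at trial onset) must be registered before
    use; selection is softmax over the q-value means at the configured
    temperature, so exact ties are resolved stochastically by the sampler.
    """

    def __init__(self, config: AgentConfig, cost_rate: float | None = None) -> None:
        self.config = config
        self.levels = np.linspace(
            config.boost_min, config.boost_max, config.n_boost_levels
        )
        self.cost_rate = config.cost_rate if cost_rate is None else float(cost_rate)
        self._state_index: dict = {}
        self._tables: list[KalmanTable] = []

    @property
    def states(self) -> list:
        return list(self._state_index)

    def register_state(self, state_id) -> None:
        if state_id not in self._state_index:
            self._state_index[state_id] = len(self._tables)
            self._tables.append(
                KalmanTable(
                    n=len(self.levels),
                    prior_mean=self.config.q_prior_mean,
                    prior_var=self.config.q_prior_var,
                    obs_noise=self.config.q_obs_noise,
                    process_noise=self.config.process_noise,
                )
            )

    def _table(self, state_id) -> KalmanTable:
        try:
            return self._tables[self._state_index[state_id]]
        except KeyError:
            raise KeyError(f"unregistered boost state: {state_id!r}") from None

    def q_means(self, state_id) -> np.ndarray:
        return self._table(state_id).means.copy()

    def selection_probs(self, state_id) -> np.ndarray:
        return softmax_probs(self._table(state_id).means, self.config.boost_temperature)

    def select_boost(self, state_id, rng: np.random.Generator) -> tuple[float, int]:
        """Sample a boost level for this condition; returns (level, index)."""
        p = self.selection_probs(state_id)
        idx = int(rng.choice(len(self.levels), p=p))
        return float(self.levels[idx]), idx

    def state_value(self, state_id) -> float:
        """Policy-weighted expected net value of facing this condition."""
        table = self._table(state_id)
        return float(self.selection_probs(state_id) @ table.means)

    def expected_outcome(self, state_id) -> float:
        """Policy-weighted expected outcome gross of boost cost."""
        table = self._table(state_id)
        p = self.selection_probs(state_id)
        return float(p @ (table.means + self.cost_rate * self.levels))

    def cost(self, level: float) -> float:
        return boost_cost(level, self.cost_rate)

    def update(self, state_id, level_idx: int, net_outcome: float) -> None:
        """Kalman-update the q-values after a trial at the chosen level.

        ``net_outcome`` must already be net of the boost cost (reward minus
        cost): the boost module learns net value directly.  Because boost is
        an ordered intensity, the outcome generalizes to neighboring levels
        with a Gaussian kernel over the level index (the kernel weight
        discounts the observation's assumed reliability), so the learned
        q-landscape is smooth along the boost axis.
        """
        table = self._table(state_id)
        width = self.config.boost_generalization
        if width <= 0:
            table.update(level_idx, net_outcome)
            return
        j = np.arange(len(self.levels))
        w = np.exp(-0.5 * ((j - level_idx) / width) ** 2)
        table.update(j, net_outcome, obs_weight=w)


def compute_neuromodulation(level: float, config: AgentConfig) -> NeuromodSignals:
    """LC and VTA outputs for a boost level: affine in boost, then clipped.

    Both outputs are non-decreasing in boost and bounded by the configured
    ranges.  With the default ``vta_coeff = 0`` the VTA output is neutral
    (1.0): outcomes reach the value filters unscaled.
    """
    if level < config.boost_min - 1e-9 or level > config.boost_max + 1e-9:
        raise ValueError(
            f"boost level {level} outside configured range "
            f"[{config.boost_min}, {config.boost_max}]"
        )
    span = config.boost_max - config.boost_min
    frac = 0.0 if span == 0 else (level - config.boost_min) / span
    lc = np.clip(
        config.lc_min + frac * (config.lc_max - config.lc_min),
        config.lc_min,
        config.lc_max,
    )
    vta = np.clip(config.vta_base + config.vta_coeff * frac, config.vta_min, config.vta_max)
    return NeuromodSignals(lc=float(lc), vta=float(vta))


def compute_dv(value_left: ValueEstimate, value_right: ValueEstimate) -> float:
    """Signed difference of option values; the sign encodes the favored side."""
    return value_left.mean - value_right.mean
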