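"""Evidence accumulation for the speeded and foraging decisions.

A discrete-time diffusion: one 'DDM cycle' is one Euler step of unit dt, so
response deadlines printed in cycles are the native clock and ``noise_sd`` is
the per-cycle standard deviation.  The drift comes from the signed option
value difference ``dv``; LC output shrinks the boundary separation (urgency)
and, in the foraging task, discounts the starting-point bias toward 'engage'.

The first-passage simulation draws noise in chunks and scans the cumulative
path, so a single run costs O(RT) rather than O(deadline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import ConfigError, DDMConfig

__all__ = [
    "DDMOutcome",
    "drift_from_dv",
    "boundary_from_lc",
    "bias_from_lc",
    "run_ddm",
    "choice_prob_upper",
]

log = logging.getLogger(__name__)

_CHUNK = 2048


@dataclass(frozen=True)
class DDMOutcome:
    """Result of one diffusion run.

    ``choice`` is +1 (upper boundary), -1 (lower) or 0 (no decision before
    the deadline).  ``rt_cycles`` is the absorption time in cycles, equal to
    ``max_cycles`` on a timeout.
    """

    choice: int
    rt_cycles: int
    timed_out: bool

    def __post_init__(self) -> None:
        if self.timed_out != (self.choice == 0):
            raise ValueError("timed_out must coincide with choice == 0")


def drift_from_dv(dv: float, config: DDMConfig) -> float:
    """Drift per cycle: sign-preserving, magnitude-monotone in dv."""
    if not np.isfinite(dv):
        raise ValueError("dv must be finite")
    return config.drift_scale * dv


def boundary_from_lc(lc: float, config: DDMConfig) -> float:
    """Boundary half-separation: shrinks linearly with LC, floored.

    At ``lc = 0`` the boundary is ``base_boundary``; at ``lc = 1`` it is
    reduced by the fraction ``boundary_lc_slope``, never below
    ``boundary_floor``.  Higher LC, closer boundaries, faster decisions.
    """
    if not np.isfinite(lc) or lc < 0:
        raise ValueError("lc must be finite and non-negative")
    boundary = config.base_boundary * (1.0 - config.boundary_lc_slope * lc)
    boundary = max(boundary, config.boundary_floor)
    if boundary <= 0:
        raise ConfigError("boundary collapsed to a non-positive value")
    return float(boundary)


def bias_from_lc(lc: float, boundary: float, config: DDMConfig) -> float:
    """Starting point toward the upper ('engage') boundary, discounted by LC.

    The speeded task configures ``bias0 = 0`` so the start is always central;
    in the foraging task the baseline engage propensity ``bias0`` shrinks
    toward 0 as LC grows.  The result is clipped (with a warning) to stay
    strictly inside the boundary.
    """
    if not np.isfinite(lc) or lc < 0:
        raise ValueError("lc must be finite and non-negative")
    bias = config.bias0 * max(0.0, 1.0 - config.bias_lc_discount * lc)
    limit = 0.98 * boundary
    if abs(bias) >= limit:
        log.warning("bias %.3f clipped to stay inside boundary %.3f", bias, boundary)
        bias = float(np.sign(bias)) * limit
    return float(bias)


def run_ddm(
    drift: float,
    boundary: float,
    bias: float,
    config: DDMConfig,
    rng: np.random.Generator,
) -> DDMOutcome:
    """Simulate one first passage of x_{t+1} = x_t + drift + noise_sd * xi_t.

    The walk starts at ``bias`` and is absorbed at +/- ``boundary``; if no
    boundary is reached within ``max_cycles`` the outcome is a timeout.
    """
    if not (np.isfinite(drift) and np.isfinite(boundary) and np.isfinite(bias)):
        raise ValueError("drift, boundary and bias must be finite")
    if boundary <= abs(bias):
        raise ValueError("boundary must exceed |bias|")
    remaining = config.max_cycles
    x0 = bias
    elapsed = 0
    while remaining > 0:
        n = min(_CHUNK, remaining)
        steps = drift + config.noise_sd * rng.standard_normal(n)
        path = x0 + np.cumsum(steps)
        hits = np.flatnonzero(np.abs(path) >= boundary)
        if hits.size:
            i = int(hits[0])
            choice = 1 if path[i] >= boundary else -1
            return DDMOutcome(choice=choice, rt_cycles=elapsed + i + 1, timed_out=False)
        x0 = float(path[-1])
        elapsed += n
        remaining -= n
    return DDMOutcome(choice=0, rt_cycles=config.max_cycles, timed_out=True)


def choice_prob_upper(drift: float, boundary: float, noise_sd: float) -> float:
    """Closed-form unbiased Wiener upper-boundary probability.

    P(upper) = 1 / (1 + exp(-2 * drift * boundary / noise_sd**2)), the
    continuous-time limit for a central starting point.  Used as an
    independent oracle for the simulated kernel, not by the simulations.
    """
    if drift == 0:
        return 0.5
    return float(1.0 / (1.0 + np.exp(-2.0 * drift * boundary / noise_sd**2)))
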