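"""The three-operator toolkit — access, amplify, average — and strategy simulators.

A cell interpreting a patterning cue is modelled as composing three elementary
operations:

* **access** — obtain a noisy estimate of a concentration; each access adds
  independent Gaussian input noise of SD ``eta0``.
* **amplify** — a deterministic input–output function, either pure linear
  amplification with gain ``lambda`` or a dynamic-range-preserving "zigzag"
  (triangle-wave) map that folds the profile onto itself ``lambda`` times.
* **average** — temporal/spatial averaging, reducing fluctuation SD by
  ``1/sqrt(n_eff)`` while leaving the mean shape intact.

:func:`simulate_strategy` composes these into the two architectures compared
throughout the package: the *direct* strategy (targets read the averaged input
morphogen) and the *two-tier* strategy (an amplified intermediate profile is
produced first, then averaged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .synthetic_data import (
    GradientSpec,
    ProfileRealization,
    ReadoutSpec,
    sample_gradient,
)

__all__ = [
    "StrategyParams",
    "access",
    "amplify_linear",
    "amplify_zigzag",
    "average",
    "simulate_strategy",
    "strategy_noise_sd",
]


@dataclass(frozen=True)
class StrategyParams:
    """Everything needed to simulate one patterning strategy.

    ``strategy`` is ``"direct"`` (the readout's gain/shape are ignored — no
    amplification tier exists) or ``"two_tier"``.
    """

    gradient: GradientSpec
    readout: ReadoutSpec
    strategy: str = "direct"

    def __post_init__(self) -> None:
        if self.strategy not in ("direct", "two_tier"):
            raise ValueError(f"strategy must be 'direct' or 'two_tier', got {self.strategy!r}")


def access(values: np.ndarray, eta0: float, seed: int | np.random.Generator) -> np.ndarray:
    """One noisy readout of a concentration profile: values + iid N(0, eta0^2)."""
    if eta0 < 0:
        raise ValueError(f"eta0 must be >= 0, got {eta0}")
    values = np.asarray(values, dtype=float)
    if eta0 == 0:
        return values.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return values + rng.normal(0.0, eta0, values.shape)


def amplify_linear(values: np.ndarray, gain: float) -> np.ndarray:
    """Pure linear amplification: elementwise multiplication by the gain."""
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    return np.asarray(values, dtype=float) * gain


def amplify_zigzag(values: np.ndarray, gain: int, c_max: float) -> np.ndarray:
    """Triangle-wave ("segmentation") readout preserving the dynamic range.

    The input is clamped to [0, c_max] and mapped through a triangle wave with
    integer gain ``lambda``: with ``t = lambda * v / c_max`` and
    ``k = floor(t)``, the output is ``(t - k) * c_max`` on rising segments
    (k even) and ``(1 - (t - k)) * c_max`` on falling ones.  The local slope
    magnitude is ``lambda`` everywhere except at fold points, and the output
    range equals the input range: the profile is folded onto itself
    ``lambda`` times.
    """
    if c_max <= 0:
        raise ValueError(f"c_max must be > 0, got {c_max}")
    if int(gain) != gain or gain < 1:
        raise ValueError(f"zigzag gain must be an integer >= 1, got {gain}")
    gain = int(gain)
    v = np.clip(np.asarray(values, dtype=float), 0.0, c_max)
    t = gain * v / c_max
    k = np.floor(t)
    frac = t - k
    out = np.where(k % 2 == 0, frac, 1.0 - frac) * c_max
    # the top of the clamped range belongs to the last segment, not a new one
    return np.where(t >= gain, (gain % 2) * c_max, out)


def average(
    sample_fn: Callable[[], np.ndarray],
    n_eff: float,
    mean_values: np.ndarray | None = None,
) -> np.ndarray:
    """Averaging operator G_{n_eff}: fluctuation SD shrinks by 1/sqrt(n_eff).

    For integer ``n_eff`` this is literally the mean of ``n_eff`` independent
    realizations drawn from ``sample_fn``.  For non-integer ``n_eff`` the
    fluctuation of a single realization around ``mean_values`` is rescaled by
    ``1/sqrt(n_eff)`` (the mean profile must then be supplied).
    """
    if n_eff < 1:
        raise ValueError(f"n_eff must be >= 1, got {n_eff}")
    if float(n_eff).is_integer():
        n = int(n_eff)
        acc = np.asarray(sample_fn(), dtype=float).copy()
        for _ in range(n - 1):
            acc += sample_fn()
        return acc / n
    if mean_values is None:
        raise ValueError("non-integer n_eff requires mean_values for fluctuation rescaling")
    sample = np.asarray(sample_fn(), dtype=float)
    return mean_values + (sample - mean_values) / np.sqrt(n_eff)


def strategy_noise_sd(params: StrategyParams) -> float:
    """Closed-form fluctuation SD of the strategy's output.

    direct:   sigma0 / sqrt(n_eff)
    two-tier: xi_lambda = lambda * sqrt((sigma0^2 + eta0^2) / n_eff)
    (for the zigzag shape the slope magnitude is also lambda, so xi is the same)
    """
    g, r = params.gradient, params.readout
    if params.strategy == "direct":
        return g.sigma0 / np.sqrt(r.n_eff)
    return r.gain * np.sqrt((g.sigma0**2 + r.eta0**2) / r.n_eff)


def strategy_mean(params: StrategyParams) -> np.ndarray:
    """Mean output profile at the gradient's cell positions."""
    g, r = params.gradient, params.readout
    base = g.mean(g.positions())
    if params.strategy == "direct":
        return base
    if r.shape == "linear":
        return amplify_linear(base, r.gain)
    return amplify_zigzag(base, int(r.gain), g.c_max)


def simulate_strategy(params: StrategyParams, seed: int | np.random.Generator) -> ProfileRealization:
    """Simulate one realization of the chosen strategy's output profile.

    direct:   c(0) = G_{n_eff}[c_hat]
    two-tier: c(lambda) = G_{n_eff}[F_lambda(c_hat + eta_hat)], with fresh
    input and access noise for each of the n_eff effective measurements.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g, r = params.gradient, params.readout

    if params.strategy == "direct":
        def draw() -> np.ndarray:
            return sample_gradient(g, rng).values
    else:
        def draw() -> np.ndarray:
            est = access(sample_gradient(g, rng).values, r.eta0, rng)
            if r.shape == "linear":
                return amplify_linear(est, r.gain)
            return amplify_zigzag(est, int(r.gain), g.c_max)

    values = average(draw, r.n_eff, mean_values=strategy_mean(params))
    return ProfileRealization(positions=g.positions(), values=values, spec=g)
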