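"""Positional-information quantities for Gaussian-noise expression profiles.

Positional information is the mutual information ``I[g_hat, x_hat]`` between a
cell's position (uniform on the analysis domain) and the noisy expression
level(s) it observes.  Three routes to it live here:

* **closed forms** for linear profiles in the small-noise limit — everything
  reduces to ``I(phi) = ln(phi) - 0.5*ln(2*pi*e)`` with an effective
  signal-to-noise ratio ``phi`` that depends on the strategy (direct or
  two-tier), the averaging depth ``n_eff``, the gain ``lambda`` and the
  access noise ``eta0``;

* :func:`info_small_noise` — the general small-noise (Fisher-information)
  expression for arbitrary differentiable multi-channel profiles, used by the
  empirical pipeline;

* :func:`mi_numeric` — an independent numeric estimator (quadrature over
  position, Monte Carlo over expression) that makes no small-noise
  assumption and is correct for non-monotonic means (zigzag, stripes) and
  joint multi-channel information.  It serves as the oracle against which
  every closed form is checked.

*Raw* information ignores the downstream readout; *accessible* information is
the information left after one more access operation adds noise ``eta0`` —
``I_acc[c*] = I_raw[c* + eta_hat]``.

All internal values are in nats; ``InfoResult.value_bits`` converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model_ops import amplify_zigzag

__all__ = [
    "LN2",
    "InfoResult",
    "Channel",
    "ProfileSet",
    "linear_profile",
    "zigzag_profile",
    "info_phi",
    "raw_info_direct",
    "raw_info_two_tier",
    "acc_info_direct",
    "acc_info_two_tier",
    "benefit_condition",
    "zigzag_info",
    "info_small_noise",
    "mi_numeric",
]

LN2 = math.log(2.0)
_HALF_LN_2PIE = 0.5 * math.log(2.0 * math.pi * math.e)


@dataclass(frozen=True)
class InfoResult:
    """An information value in nats, with provenance.

    ``method`` is one of ``closed_form``, ``small_noise`` or ``numeric``;
    ``mc_stderr`` is the Monte-Carlo standard error (0 for deterministic
    methods).  ``value_bits`` is always ``value / ln 2``.
    """

    value: float
    method: str
    mc_stderr: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("closed_form", "small_noise", "numeric"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.mc_stderr < 0:
            raise ValueError("mc_stderr must be >= 0")

    @property
    def value_bits(self) -> float:
        return self.value / LN2

    def to_dict(self) -> dict:
        return {
            "value_nats": self.value,
            "value_bits": self.value_bits,
            "method": self.method,
            "stderr": self.mc_stderr,
        }


@dataclass(frozen=True)
class Channel:
    """One expression channel: mean and noise-SD as functions of position.

    ``dmean`` (the mean's derivative) is optional; when absent it is obtained
    by central finite differences on a fine grid.
    """

    name: str
    mean: Callable[[np.ndarray], np.ndarray]
    sd: Callable[[np.ndarray], np.ndarray]
    dmean: Callable[[np.ndarray], np.ndarray] | None = None

    def slope(self, x: np.ndarray, h: float) -> np.ndarray:
        if self.dmean is not None:
            return np.asarray(self.dmean(x), dtype=float)
        return (np.asarray(self.mean(x + h)) - np.asarray(self.mean(x - h))) / (2.0 * h)


@dataclass(frozen=True)
class ProfileSet:
    """A set of channels over a common position domain with a uniform prior."""

    channels: tuple[Channel, ...]
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("ProfileSet needs at least one channel")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"domain must be increasing, got {self.domain}")

    @property
    def length(self) -> float:
        return self.domain[1] - self.domain[0]

    def restrict(self, domain: tuple[float, float]) -> "ProfileSet":
        lo, hi = domain
        if lo < self.domain[0] - 1e-12 or hi > self.domain[1] + 1e-12:
            raise ValueError(
                f"requested domain {domain} is outside the profile domain {self.domain}"
            )
        return ProfileSet(channels=self.channels, domain=(float(lo), float(hi)))

    def scaled(self, factor: float) -> "ProfileSet":
        """Multiply every mean and SD by a constant (units change only)."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        chans = tuple(
            Channel(
                name=c.name,
                mean=(lambda f: (lambda x: factor * np.asarray(f(x))))(c.mean),
                sd=(lambda f: (lambda x: factor * np.asarray(f(x))))(c.sd),
                dmean=None if c.dmean is None
                else (lambda f: (lambda x: factor * np.asarray(f(x))))(c.dmean),
            )
            for c in self.channels
        )
        return ProfileSet(channels=chans, domain=self.domain)

    def noiseless(self) -> "ProfileSet":
        """Same means, every channel SD forced to zero."""
        chans = tuple(
            Channel(name=c.name, mean=c.mean, sd=(lambda x: np.zeros_like(np.asarray(x, float))),
                    dmean=c.dmean)
            for c in self.channels
        )
        return ProfileSet(channels=chans, domain=self.domain)


def linear_profile(c_max: float, sigma: float, length: float = 1.0) -> ProfileSet:
    """A single linear channel: mean x*(c_max/length), constant SD, on [0, length]."""
    if c_max <= 0 or length <= 0:
        raise ValueError("c_max and length must be > 0")
    slope = c_max / length
    return ProfileSet(
        channels=(
            Channel(
                name="linear",
                mean=lambda x: slope * np.asarray(x, float),
                sd=lambda x: np.full_like(np.asarray(x, float), float(sigma)),
                dmean=lambda x: np.full_like(np.asarray(x, float), slope),
            ),
        ),
        domain=(0.0, float(length)),
    )


def zigzag_profile(c_max: float, gain: int, sigma: float, length: float = 1.0) -> ProfileSet:
    """A single zigzag channel: triangle-wave mean of range c_max, constant SD."""
    if c_max <= 0 or length <= 0:
        raise ValueError("c_max and length must be > 0")

    def mean(x: np.ndarray) -> np.ndarray:
        lin = np.asarray(x, float) / length * c_max
        return amplify_zigzag(lin, gain, c_max)

    return ProfileSet(
        channels=(
            Channel(
                name=f"zigzag{gain}",
                mean=mean,
                sd=lambda x: np.full_like(np.asarray(x, float), float(sigma)),
            ),
        ),
        domain=(0.0, float(length)),
    )


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def info_phi(phi: float) -> InfoResult:
    """I(phi) = ln(phi / sqrt(2*pi*e)): small-noise positional information of a
    linear profile with dynamic-range-to-noise ratio phi."""
    if not phi > 0:
        raise ValueError(f"phi must be > 0, got {phi}")
    return InfoResult(value=math.log(phi) - _HALF_LN_2PIE, method="closed_form")


def _check_domain(c_max: float, sigma0: float, eta0: float, n_eff: float, gain: float = 1.0) -> None:
    if c_max <= 0:
        raise ValueError(f"c_max must be > 0, got {c_max}")
    if sigma0 < 0 or eta0 < 0:
        raise ValueError("noise SDs must be >= 0")
    if n_eff < 1:
        raise ValueError(f"n_eff must be >= 1, got {n_eff}")
    if gain < 1:
        raise ValueError(f"gain must be >= 1, got {gain}")


def raw_info_direct(c_max: float, sigma0: float, n_eff: float = 1.0) -> InfoResult:
    """Raw information of the averaged input morphogen: I(c_max*sqrt(n_eff)/sigma0)."""
    _check_domain(c_max, sigma0, 0.0, n_eff)
    if sigma0 == 0:
        raise ValueError("raw information of a noiseless profile is infinite")
    return info_phi(c_max * math.sqrt(n_eff) / sigma0)


def raw_info_two_tier(
    c_max: float, sigma0: float, eta0: float, n_eff: float = 1.0, gain: float = 1.0
) -> InfoResult:
    """Raw information of the amplified-and-averaged profile.

    I(c_max * sqrt(n_eff) / sqrt(sigma0^2 + eta0^2)) — the gain cancels, which
    is exactly why raw information cannot explain the benefit of amplification.
    """
    _check_domain(c_max, sigma0, eta0, n_eff, gain)
    denom = math.hypot(sigma0, eta0)
    if denom == 0:
        raise ValueError("raw information of a noiseless profile is infinite")
    return info_phi(c_max * math.sqrt(n_eff) / denom)


def acc_info_direct(c_max: float, sigma0: float, eta0: float, n_eff: float = 1.0) -> InfoResult:
    """Accessible information of the direct strategy:
    I(c_max / sqrt(sigma0^2/n_eff + eta0^2))."""
    _check_domain(c_max, sigma0, eta0, n_eff)
    denom = math.sqrt(sigma0**2 / n_eff + eta0**2)
    if denom == 0:
        raise ValueError("accessible information is infinite for a fully noiseless channel")
    return info_phi(c_max / denom)


def acc_info_two_tier(
    c_max: float, sigma0: float, eta0: float, n_eff: float = 1.0, gain: float = 1.0
) -> InfoResult:
    """Accessible information of the two-tier strategy:
    I(c_max / sqrt((sigma0^2+eta0^2)/n_eff + eta0^2/gain^2)).

    The access noise eta0 enters twice — once inside the averaged first tier,
    once for the final readout — but amplification suppresses the second
    occurrence by 1/gain^2, so the value is strictly increasing in the gain
    whenever eta0 > 0.
    """
    _check_domain(c_max, sigma0, eta0, n_eff, gain)
    denom = math.sqrt((sigma0**2 + eta0**2) / n_eff + eta0**2 / gain**2)
    if denom == 0:
        raise ValueError("accessible information is infinite for a fully noiseless channel")
    return info_phi(c_max / denom)


def benefit_condition(eta0: float, n_eff: float, gain: float) -> tuple[bool, float]:
    """When does the extra noisy amplification tier help?

    Returns ``(beneficial, margin)`` with
    ``margin = eta0^2 * (1 - 1/n_eff - 1/gain^2)``; the tier is beneficial iff
    the margin is positive.  The margin's sign equals the sign of
    ``acc_info_two_tier - acc_info_direct`` for all valid parameters, and it
    can never be positive with ``n_eff = 1`` (no averaging) or ``gain = 1``
    (no amplification).
    """
    if eta0 < 0 or n_eff < 1 or gain < 1:
        raise ValueError("require eta0 >= 0, n_eff >= 1, gain >= 1")
    margin = eta0**2 * (1.0 - 1.0 / n_eff - 1.0 / gain**2)
    return margin > 0, margin


def zigzag_info(base: InfoResult, gain: int) -> InfoResult:
    """Information of the zigzag-folded profile: the base value minus ln(gain).

    Folding the profile onto itself ``gain`` times reuses each output level at
    ``gain`` locations, costing exactly ln(gain) nats; the reduction applies
    identically to raw and accessible information.
    """
    if int(gain) != gain or gain < 1:
        raise ValueError(f"zigzag gain must be an integer >= 1, got {gain}")
    return InfoResult(
        value=base.value - math.log(int(gain)),
        method=base.method,
        mc_stderr=base.mc_stderr,
    )


# ---------------------------------------------------------------------------
# Small-noise (Fisher-information) expression for arbitrary profiles
# ---------------------------------------------------------------------------


def _total_variances(
    profiles: ProfileSet,
    x: np.ndarray,
    eta0: float,
    fractional: bool,
) -> list[np.ndarray]:
    out = []
    for c in profiles.channels:
        sd = np.asarray(c.sd(x), dtype=float)
        if np.any(sd < 0):
            raise ValueError(f"channel {c.name!r}: negative noise SD")
        extra = eta0 * np.asarray(c.mean(x), dtype=float) if fractional else eta0
        out.append(sd**2 + np.asarray(extra) ** 2 * np.ones_like(sd))
    return out


def info_small_noise(
    profiles: ProfileSet,
    extra_noise: float = 0.0,
    n_grid: int = 2001,
    fractional: bool = False,
) -> InfoResult:
    """Small-noise positional information of a multi-channel profile set.

    The positional error aggregates Fisher information across channels,
    ``sigma_x(x)^-2 = sum_i (dg_i/dx)^2 / (sigma_i(x)^2 + eta0^2)``, and the
    information is ``ln(L) - <ln(sqrt(2*pi*e) * sigma_x(x))>`` with the average
    over a uniform position prior on the domain.  For a single linear channel
    this reproduces ``info_phi`` exactly.

    With ``fractional=True`` the extra readout noise is ``eta0 * mean_i(x)``
    per channel instead of the absolute ``eta0``.
    """
    if extra_noise < 0:
        raise ValueError("extra_noise must be >= 0")
    lo, hi = profiles.domain
    h = (hi - lo) / n_grid
    x = lo + (np.arange(n_grid) + 0.5) * h

    variances = _total_variances(profiles, x, extra_noise, fractional)
    fisher = np.zeros_like(x)
    for c, var in zip(profiles.channels, variances):
        if np.any(var <= 0):
            raise ValueError(
                f"channel {c.name!r} has zero total variance somewhere; "
                "provide extra_noise > 0 or a small regularizing SD"
            )
        fisher += c.slope(x, h) ** 2 / var

    if np.all(fisher == 0):
        raise ValueError("zero Fisher information everywhere: information undefined")
    zero_run = np.flatnonzero(np.convolve((fisher == 0).astype(int), [1, 1], "valid") == 2)
    if zero_run.size:
        raise ValueError(
            "zero Fisher information on a subinterval: small-noise information undefined"
        )

    with np.errstate(divide="ignore"):
        ln_sigma_x = -0.5 * np.log(fisher)  # integrable log singularities allowed
    mean_ln = np.mean(np.where(np.isfinite(ln_sigma_x), ln_sigma_x, 0.0))
    # isolated zeros of the Fisher information contribute -inf * 0 weight in the
    # limit; with a midpoint grid they are excluded, matching the integrable
    # singularity of ln|x - x0|
    value = math.log(hi - lo) - (_HALF_LN_2PIE + mean_ln)
    return InfoResult(value=value, method="small_noise")


# ---------------------------------------------------------------------------
# Numeric oracle
# ---------------------------------------------------------------------------


def mi_numeric(
    profiles: ProfileSet,
    extra_noise: float = 0.0,
    n_grid: int = 512,
    n_mc: int = 20000,
    seed: int | np.random.Generator = 0,
    n_batches: int = 20,
    fractional: bool = False,
    chunk: int = 2000,
) -> InfoResult:
    """Monte-Carlo / quadrature estimate of I[{g_i(x) + noise}, x].

    Position is uniform on the domain; channel *i* adds independent Gaussian
    noise of total variance ``sigma_i(x)^2 + eta0^2``.  The conditional entropy
    is computed by quadrature (it is exact for Gaussian noise); the marginal
    entropy is estimated by Monte Carlo draws of ``(x, g)`` with the mixture
    density ``p(g) = <p(g|x)>_x`` evaluated by midpoint quadrature over an
    ``n_grid``-point position grid.  ``mc_stderr`` comes from batching the MC
    draws.  No small-noise assumption is made, so the estimator is valid for
    non-monotonic means (zigzag, stripes) and joint multi-channel sets.

    The quadrature grid must resolve the posterior width: choose
    ``n_grid >= ~1.5 * L / min_x sigma_x(x)`` for accurate results.
    """
    if extra_noise < 0:
        raise ValueError("extra_noise must be >= 0")
    if n_mc < n_batches:
        raise ValueError("n_mc must be >= n_batches")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = profiles.domain
    length = hi - lo

    xg = lo + (np.arange(n_grid) + 0.5) * length / n_grid
    grid_means = []
    grid_vars = _total_variances(profiles, xg, extra_noise, fractional)
    for c, var in zip(profiles.channels, grid_vars):
        if np.any(var <= 0):
            raise ValueError(
                f"channel {c.name!r} has zero total variance somewhere; "
                "provide extra_noise > 0 or a small regularizing SD"
            )
        grid_means.append(np.asarray(c.mean(xg), dtype=float))

    # conditional entropy by quadrature: H(g|x) = < sum_i 0.5*ln(2*pi*e*var_i(x)) >
    h_cond = float(np.mean(sum(0.5 * np.log(2 * np.pi * np.e * v) for v in grid_vars)))

    # draws
    xs = rng.uniform(lo, hi, n_mc)
    draw_vars = _total_variances(profiles, xs, extra_noise, fractional)
    gs = [
        np.asarray(c.mean(xs), dtype=float) + rng.normal(0.0, 1.0, n_mc) * np.sqrt(v)
        for c, v in zip(profiles.channels, draw_vars)
    ]

    log_p = np.empty(n_mc)
    const = -0.5 * sum(np.log(2 * np.pi * v) for v in grid_vars)  # per grid point
    for i0 in range(0, n_mc, chunk):
        sl = slice(i0, min(i0 + chunk, n_mc))
        ll = np.zeros((sl.stop - sl.start, n_grid))
        for g, gm, gv in zip(gs, grid_means, grid_vars):
            d = g[sl][:, None] - gm[None, :]
            ll -= 0.5 * d * d / gv[None, :]
        ll += const[None, :]
        m = ll.max(axis=1)
        log_p[sl] = m + np.log(np.exp(ll - m[:, None]).sum(axis=1)) - math.log(n_grid)

    h_marg_terms = -log_p
    h_marg = float(h_marg_terms.mean())
    batch_means = h_marg_terms[: n_mc - n_mc % n_batches].reshape(n_batches, -1).mean(axis=1)
    stderr = float(batch_means.std(ddof=1) / math.sqrt(n_batches))

    return InfoResult(value=h_marg - h_cond, method="numeric", mc_stderr=stderr)
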