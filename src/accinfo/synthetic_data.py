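"""Synthetic inputs: noisy linear morphogen gradients and embryo-like nucleus tables.

Two generators cover everything the analysis pipeline consumes:

* :func:`sample_gradient` draws one realization of the abstract input morphogen —
  a linear mean profile ``(x/L) * c_max`` with iid Gaussian fluctuations of
  constant magnitude ``sigma0``, uncorrelated between cells.

* :func:`generate_embryo` builds a nucleus table emulating the geometry of the
  fly blastoderm around the anterior–posterior (AP) mid-body region: two
  gap-gene-like channels forming opposing sigmoidal boundaries inside the
  region of interest (ROI), and a steeper, noisier pair-rule-like channel with
  a trough between two stripes.  Nuclei form a regular grid of ``n_ap`` AP rows
  by ``n_dv`` dorsal–ventral (DV) columns; expression noise is independent
  across nuclei and genes, so nuclei sharing an AP row but sitting in adjacent
  DV columns are exchangeable replicates — the property the neighbor-based
  noise estimator relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GradientSpec",
    "ReadoutSpec",
    "ProfileRealization",
    "SigmoidShape",
    "StripeShape",
    "NoiseSpec",
    "GeneSpec",
    "EmbryoSpec",
    "default_embryo_spec",
    "sample_gradient",
    "generate_embryo",
    "generate_embryos",
    "roi_slope_check",
]


@dataclass(frozen=True)
class GradientSpec:
    """Parameters of the noisy linear input morphogen.

    Attributes
    ----------
    L : float
        Axis length (arbitrary units, > 0).
    c_max : float
        Maximal mean concentration (concentration units, > 0).
    sigma0 : float
        Input noise SD, position-independent and uncorrelated between cells.
    n_cells : int
        Number of cells along the axis (>= 2).
    """

    L: float
    c_max: float
    sigma0: float
    n_cells: int

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"axis length L must be > 0, got {self.L}")
        if not self.c_max > 0:
            raise ValueError(f"c_max must be > 0, got {self.c_max}")
        if self.sigma0 < 0:
            raise ValueError(f"sigma0 must be >= 0, got {self.sigma0}")
        if int(self.n_cells) != self.n_cells or self.n_cells < 2:
            raise ValueError(f"n_cells must be an integer >= 2, got {self.n_cells}")

    def positions(self) -> np.ndarray:
        """Cell positions, evenly spaced over [0, L] inclusive."""
        return np.linspace(0.0, self.L, int(self.n_cells))

    def mean(self, x: np.ndarray) -> np.ndarray:
        """Mean profile (x/L) * c_max."""
        return np.asarray(x, dtype=float) / self.L * self.c_max


@dataclass(frozen=True)
class ReadoutSpec:
    """One tier of interpretation.

    Attributes
    ----------
    eta0 : float
        Input-noise SD of a single 'access' operation (concentration units).
    gain : float
        Amplification factor lambda (>= 1; must be an integer for zigzag).
    shape : str
        Input–output function shape: ``"linear"`` or ``"zigzag"``.
    n_eff : float
        Effective number of independent measurements (>= 1); 1 means no
        averaging.  Real values are allowed.
    """

    eta0: float
    gain: float = 1.0
    shape: str = "linear"
    n_eff: float = 1.0

    def __post_init__(self) -> None:
        if self.eta0 < 0:
            raise ValueError(f"eta0 must be >= 0, got {self.eta0}")
        if self.gain < 1:
            raise ValueError(f"gain must be >= 1, got {self.gain}")
        if self.shape not in ("linear", "zigzag"):
            raise ValueError(f"shape must be 'linear' or 'zigzag', got {self.shape!r}")
        if self.shape == "zigzag" and int(self.gain) != self.gain:
            raise ValueError(f"zigzag readout requires integer gain, got {self.gain}")
        if self.n_eff < 1:
            raise ValueError(f"n_eff must be >= 1, got {self.n_eff}")


@dataclass
class ProfileRealization:
    """A sampled concentration profile: one value per cell."""

    positions: np.ndarray
    values: np.ndarray
    spec: GradientSpec | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_index": np.arange(self.positions.size),
                "x": self.positions,
                "value": self.values,
            }
        )


def sample_gradient(spec: GradientSpec, seed: int | np.random.Generator) -> ProfileRealization:
    """Draw one realization of the noisy linear gradient.

    ``values_i = (x_i / L) * c_max + eps_i`` with ``eps_i`` iid Gaussian of
    SD ``sigma0``.  Deterministic for a fixed integer seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = spec.positions()
    values = spec.mean(x) + rng.normal(0.0, spec.sigma0, x.size)
    return ProfileRealization(positions=x, values=values, spec=spec)


# ---------------------------------------------------------------------------
# Embryo-like nucleus tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidShape:
    """Logistic mean profile ``basal + amplitude / (1 + exp(s*(x-midpoint)/width))``.

    ``decreasing=True`` gives a high-anterior (Hb-like) boundary, ``False`` a
    high-posterior (Kr-like) one.
    """

    midpoint: float
    width: float
    decreasing: bool
    amplitude: float = 1.0
    basal: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.amplitude <= 0 or self.basal < 0:
            raise ValueError("sigmoid shape requires width>0, amplitude>0, basal>=0")

    def mean(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sgn = 1.0 if self.decreasing else -1.0
        return self.basal + self.amplitude / (1.0 + np.exp(sgn * (x - self.midpoint) / self.width))

    def slope(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sgn = 1.0 if self.decreasing else -1.0
        p = 1.0 / (1.0 + np.exp(sgn * (x - self.midpoint) / self.width))
        return -sgn * self.amplitude * p * (1.0 - p) / self.width


@dataclass(frozen=True)
class StripeShape:
    """Sum of Gaussian stripes over a basal level; a trough forms between centers."""

    centers: tuple[float, ...]
    widths: tuple[float, ...]
    amplitudes: tuple[float, ...]
    basal: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths and amplitudes must have equal length")
        if any(w <= 0 for w in self.widths) or any(a <= 0 for a in self.amplitudes):
            raise ValueError("stripe widths and amplitudes must be > 0")
        if self.basal < 0:
            raise ValueError("basal level must be >= 0")

    def mean(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.basal, dtype=float)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            out += a * np.exp(-0.5 * ((x - c) / w) ** 2)
        return out

    def slope(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            out += -a * (x - c) / w**2 * np.exp(-0.5 * ((x - c) / w) ** 2)
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Per-gene expression-noise model: SD as a function of normalized AP position.

    kind:
        * ``"constant"`` — sd(x) = params["sd"]
        * ``"affine"``   — sd(x) = params["intercept"] + params["slope"] * x
        * ``"fractional"`` — sd(x) = params["coeff"] * mean(x)
    """

    kind: str = "constant"
    params: Mapping[str, float] = field(default_factory=lambda: {"sd": 0.05})

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "affine", "fractional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def sd(self, x: np.ndarray, mean: np.ndarray | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            out = np.full_like(x, float(self.params["sd"]))
        elif self.kind == "affine":
            out = float(self.params["intercept"]) + float(self.params["slope"]) * x
        else:  # fractional
            if mean is None:
                raise ValueError("fractional noise requires the mean profile")
            out = float(self.params["coeff"]) * np.asarray(mean, dtype=float)
        if np.any(out < 0):
            raise ValueError("noise SD must be >= 0 everywhere")
        return out


@dataclass(frozen=True)
class GeneSpec:
    """A gene's mean shape and noise model."""

    shape: SigmoidShape | StripeShape
    noise: NoiseSpec


@dataclass(frozen=True)
class EmbryoSpec:
    """Synthetic embryo: gene shapes, noise models and nucleus-grid geometry.

    The grid spans ``x_range`` (normalized AP fractions) with ``n_ap`` rows of
    ``n_dv`` nuclei each.  ``roi`` is the interval in which the gap-like genes
    form opposing boundaries and the pair-rule-like gene its trough.
    """

    genes: Mapping[str, GeneSpec]
    n_ap: int = 200
    n_dv: int = 20
    roi: tuple[float, float] = (0.37, 0.47)
    x_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_ap < 2 or self.n_dv < 1:
            raise ValueError("need n_ap >= 2 and n_dv >= 1")
        lo, hi = self.roi
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"roi bounds must satisfy 0 <= lo < hi <= 1, got {self.roi}")
        if not self.x_range[0] < self.x_range[1]:
            raise ValueError("x_range must be increasing")
        xs = np.linspace(*self.x_range, 512)
        for name, g in self.genes.items():
            if np.any(g.shape.mean(xs) < 0):
                raise ValueError(f"gene {name!r}: mean profile is negative somewhere")

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    def ap_positions(self) -> np.ndarray:
        """Row midpoints, avoiding the exact range endpoints."""
        lo, hi = self.x_range
        step = (hi - lo) / self.n_ap
        return lo + (np.arange(self.n_ap) + 0.5) * step

    def mean_function(self, gene: str) -> Callable[[np.ndarray], np.ndarray]:
        return self.genes[gene].shape.mean

    def slope_function(self, gene: str) -> Callable[[np.ndarray], np.ndarray]:
        return self.genes[gene].shape.slope

    def sd_function(self, gene: str) -> Callable[[np.ndarray], np.ndarray]:
        g = self.genes[gene]
        return lambda x: g.noise.sd(x, mean=g.shape.mean(x))


def default_embryo_spec(
    n_ap: int = 200,
    n_dv: int = 20,
    gap_sd: float = 0.05,
    stripe_sd: float = 0.10,
) -> EmbryoSpec:
    """The canonical Hb/Kr/Eve-like embryo.

    Geometry (normalized AP fractions, expression in units of each gene's
    idealized maximum):

    * ``hb``  — decreasing logistic boundary at 0.42, width 0.025, range
      0.2–1.0, constant SD 0.05.
    * ``kr``  — the mirror-image increasing boundary (same midpoint/width/SD),
      so the two gap-like genes form opposing boundaries across the ROI
      (0.37, 0.47).
    * ``eve`` — two Gaussian stripes (centers 0.36 and 0.48, width 0.015)
      on a 0.4 basal level, giving a trough centered in the ROI, with maximum
      ROI slope about 3x that of the gap-like genes and SD 0.10 (2x the gap
      noise) — steeper but noisier, the configuration in which a downstream
      tier pays for its precision in accessibility.

    Basal levels keep every mean >= 4 SD above zero so that additive Gaussian
    noise essentially never drives expression negative (background-subtracted
    intensities; rare negative draws are clipped at 0).
    """
    genes = {
        "hb": GeneSpec(
            shape=SigmoidShape(midpoint=0.42, width=0.025, decreasing=True,
                               amplitude=0.8, basal=0.2),
            noise=NoiseSpec("constant", {"sd": gap_sd}),
        ),
        "kr": GeneSpec(
            shape=SigmoidShape(midpoint=0.42, width=0.025, decreasing=False,
                               amplitude=0.8, basal=0.2),
            noise=NoiseSpec("constant", {"sd": gap_sd}),
        ),
        "eve": GeneSpec(
            shape=StripeShape(centers=(0.36, 0.48), widths=(0.015, 0.015),
                              amplitudes=(0.6, 0.6), basal=0.4),
            noise=NoiseSpec("constant", {"sd": stripe_sd}),
        ),
    }
    return EmbryoSpec(genes=genes, n_ap=n_ap, n_dv=n_dv)


def generate_embryo(spec: EmbryoSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Generate one synthetic embryo as a nucleus table.

    Returns a DataFrame with columns ``nucleus_id, x_ap, dv_index`` plus one
    column per gene.  Expression of gene *g* in each nucleus is
    ``mean_g(x_ap) + Gaussian(0, sd_g(x_ap)^2)``, independent across nuclei
    and genes; negative draws (>= 4 SD events under the default spec) are
    clipped at 0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x_rows = spec.ap_positions()
    x_ap = np.repeat(x_rows, spec.n_dv)
    dv = np.tile(np.arange(spec.n_dv), spec.n_ap)
    table = pd.DataFrame(
        {
            "nucleus_id": np.arange(x_ap.size),
            "x_ap": x_ap,
            "dv_index": dv,
        }
    )
    for name in spec.gene_names:
        mean = spec.mean_function(name)(x_ap)
        sd = spec.sd_function(name)(x_ap)
        expr = mean + rng.normal(0.0, 1.0, x_ap.size) * sd
        table[name] = np.clip(expr, 0.0, None)
    return table


def generate_embryos(
    spec: EmbryoSpec, n_embryos: int, seed: int
) -> list[pd.DataFrame]:
    """Generate a replicate set of embryos with independent child RNG streams."""
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_embryos)
    return [generate_embryo(spec, np.random.default_rng(s)) for s in children]


def roi_slope_check(spec: EmbryoSpec, steep_gene: str, reference_genes: list[str]) -> bool:
    """True if ``steep_gene``'s max |slope| over the ROI exceeds each reference's.

    This is the geometric premise behind the crossing-point analysis: the
    downstream channel must be steeper than its inputs inside the ROI.
    """
    xs = np.linspace(*spec.roi, 2048)
    steep = np.max(np.abs(spec.slope_function(steep_gene)(xs)))
    return all(
        steep > np.max(np.abs(spec.slope_function(g)(xs))) for g in reference_genes
    )
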