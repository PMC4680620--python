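"""Embryo-analysis pipeline: nucleus tables -> accessible-information curves.

The chain mirrors how one would analyse triple-immunostained embryos projected
onto the AP axis:

1. :func:`estimate_neighbor_noise` — expression noise per gene from the RMS
   difference between a nucleus and its immediate dorsal/ventral neighbour
   (nuclei in the same AP row see the same mean, so the difference isolates
   the noise; per-nucleus SD = RMS / sqrt(2));
2. :func:`fit_idealized_profile` — smoothing-spline fits of the mean profile
   and of the neighbor-noise SD, normalized so each gene's idealized maximum
   over the full axis is 1;
3. :func:`roi_restrict` — condition the position prior on the region of
   interest where the two gap-like genes form opposing boundaries;
4. :func:`acc_info_curve` — accessible information of a profile set as a
   function of the readout noise eta0, treated as a variable parameter;
5. :func:`noiseless_pair_bound` — the best-case curve for a strategy lacking
   the downstream gene: the gap pair with expression noise set to zero, so
   only eta0 remains (infinite at eta0 = 0);
6. :func:`find_crossing` — the smallest eta0 at which the full triplet's
   curve meets or exceeds that bound;
7. :func:`run_pipeline` — the whole chain on one or more nucleus tables (or
   an embryo spec to generate them), emitting a JSON-ready report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq

from . import information as info
from .information import Channel, ProfileSet
from .synthetic_data import EmbryoSpec, generate_embryos

__all__ = [
    "NoiseProfileEstimate",
    "ExpressionProfile",
    "InfoCurve",
    "CrossingResult",
    "PipelineConfig",
    "estimate_neighbor_noise",
    "fit_idealized_profile",
    "roi_restrict",
    "acc_info_curve",
    "noiseless_pair_bound",
    "find_crossing",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("nucleus_id", "x_ap", "dv_index")


@dataclass
class NoiseProfileEstimate:
    """Neighbor-difference noise estimate for one gene, per AP bin."""

    gene: str
    bin_centers: np.ndarray
    rms: np.ndarray          # RMS of adjacent-DV expression differences
    sd: np.ndarray           # per-nucleus SD = rms / sqrt(2)
    n_pairs: np.ndarray
    valid: np.ndarray        # bins with >= 2 pairs
    replicate_sd: np.ndarray | None = None  # spread of per-table SD estimates

    def __post_init__(self) -> None:
        if np.any(self.sd[self.valid] < 0):
            raise ValueError("SD estimates must be >= 0")


@dataclass
class ExpressionProfile:
    """A fitted channel: mean and noise-SD splines over a domain, max-normalized."""

    gene: str
    mean: Callable[[np.ndarray], np.ndarray]
    sd: Callable[[np.ndarray], np.ndarray]
    dmean: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    norm: float  # raw-units value that was mapped to 1

    def channel(self) -> Channel:
        return Channel(name=self.gene, mean=self.mean, sd=self.sd, dmean=self.dmean)


@dataclass
class InfoCurve:
    """Information (bits and nats) versus readout noise eta0.

    ``evaluate(eta0)`` recomputes a point in nats; infinite entries (the
    noiseless bound at eta0 = 0) are stored as ``inf`` sentinels and flagged.
    """

    eta0: np.ndarray
    nats: np.ndarray
    evaluate: Callable[[float], float]
    label: str = ""

    @property
    def bits(self) -> np.ndarray:
        return self.nats / info.LN2

    @property
    def infinite(self) -> np.ndarray:
        return ~np.isfinite(self.nats)


@dataclass
class CrossingResult:
    """Location of the crossing between the triplet curve and the pair bound."""

    eta0_star: float | None
    bracket: tuple[float, float] | None
    bound_label: str = "noiseless_pair"
    triplet_label: str = "triplet"

    @property
    def found(self) -> bool:
        return self.eta0_star is not None


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings.

    ``inputs`` are the gap-like genes (the hypothetical noiseless pair);
    ``intermediate`` is the downstream pair-rule-like gene completing the
    triplet.  ``eta0_grid`` always gets an implicit leading 0 entry for the
    divergent bound sentinel.  ``noise_mode`` is ``"absolute"`` (extra
    readout noise eta0 in max-normalized expression units) or ``"fractional"``
    (eta0 * mean(x)).
    """

    inputs: tuple[str, str] = ("hb", "kr")
    intermediate: str = "eve"
    roi: tuple[float, float] = (0.37, 0.47)
    noise_bins: int = 50
    eta0_grid: tuple[float, ...] = tuple(np.geomspace(3e-3, 3.0, 25))
    smoothing: float | None = None  # None -> generalized cross-validation
    noise_mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.noise_mode not in ("absolute", "fractional"):
            raise ValueError("noise_mode must be 'absolute' or 'fractional'")
        if any(e <= 0 for e in self.eta0_grid) or list(self.eta0_grid) != sorted(self.eta0_grid):
            raise ValueError("eta0_grid must be positive and increasing")

    @property
    def genes(self) -> tuple[str, ...]:
        return (*self.inputs, self.intermediate)


def _as_tables(tables: pd.DataFrame | Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    if isinstance(tables, pd.DataFrame):
        return [tables]
    return list(tables)


def _validate_table(table: pd.DataFrame, gene: str | None = None) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus table is missing columns {missing}")
    if gene is not None and gene not in table.columns:
        raise ValueError(f"gene {gene!r} not present in nucleus table")


def estimate_neighbor_noise(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    gene: str,
    bins: int | np.ndarray = 50,
    domain: tuple[float, float] | None = None,
) -> NoiseProfileEstimate:
    """Expression noise from immediate dorsal/ventral neighbor differences.

    For every pair of nuclei sharing an AP row (identical ``x_ap``) with
    adjacent ``dv_index``, the expression difference is recorded; per AP bin
    the RMS difference and the implied per-nucleus SD (RMS/sqrt(2), two iid
    measurements) are returned, pooled over all supplied tables.  When several
    tables (embryo replicates) are given, ``replicate_sd`` holds the standard
    deviation of per-table SD estimates per bin.
    """
    tables = _as_tables(tables)
    diffs_all: list[np.ndarray] = []
    xs_all: list[np.ndarray] = []
    table_idx: list[np.ndarray] = []
    for t_i, table in enumerate(tables):
        _validate_table(table, gene)
        if table["dv_index"].nunique() < 2:
            raise ValueError("neighbor-noise estimation needs at least 2 DV columns")
        t = table.sort_values(["x_ap", "dv_index"], kind="mergesort")
        same_row = t["x_ap"].to_numpy()[1:] == t["x_ap"].to_numpy()[:-1]
        adjacent = np.diff(t["dv_index"].to_numpy()) == 1
        keep = same_row & adjacent
        d = np.diff(t[gene].to_numpy())[keep]
        diffs_all.append(d)
        xs_all.append(t["x_ap"].to_numpy()[:-1][keep])
        table_idx.append(np.full(d.size, t_i))

    diffs = np.concatenate(diffs_all)
    xs = np.concatenate(xs_all)
    t_idx = np.concatenate(table_idx)

    if domain is None:
        domain = (float(xs.min()), float(np.nextafter(xs.max(), np.inf)))
    edges = np.asarray(bins, dtype=float) if not np.isscalar(bins) else np.linspace(
        domain[0], domain[1], int(bins) + 1
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(xs, edges) - 1
    nb = centers.size

    rms = np.full(nb, np.nan)
    n_pairs = np.zeros(nb, dtype=int)
    rep_sd = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        n_pairs[b] = int(sel.sum())
        if n_pairs[b] >= 2:
            rms[b] = float(np.sqrt(np.mean(diffs[sel] ** 2)))
            if len(tables) > 1:
                per_table = [
                    np.sqrt(np.mean(diffs[sel & (t_idx == ti)] ** 2)) / math.sqrt(2.0)
                    for ti in range(len(tables))
                    if (sel & (t_idx == ti)).sum() >= 2
                ]
                if len(per_table) > 1:
                    rep_sd[b] = float(np.std(per_table, ddof=1))
    valid = n_pairs >= 2
    return NoiseProfileEstimate(
        gene=gene,
        bin_centers=centers,
        rms=rms,
        sd=rms / math.sqrt(2.0),
        n_pairs=n_pairs,
        valid=valid,
        replicate_sd=rep_sd if len(tables) > 1 else None,
    )


def fit_idealized_profile(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    gene: str,
    domain: tuple[float, float] | None = None,
    smoothing: float | None = None,
    noise_bins: int = 50,
) -> ExpressionProfile:
    """Idealized Gaussian-noise profile: smoothing splines for mean and SD.

    The mean is fit to per-AP-row average expression (pooled over tables); the
    noise SD is fit to the neighbor-difference estimates on ``noise_bins``
    bins.  ``smoothing`` is the spline penalty ``lam`` (None = generalized
    cross-validation).  Both curves are then divided by the fitted mean's
    maximum over the full data domain, so the idealized maximum is 1.
    """
    tables = _as_tables(tables)
    for t in tables:
        _validate_table(t, gene)
    pooled = pd.concat(tables, ignore_index=True)
    by_row = pooled.groupby("x_ap")[gene].mean()
    x_rows = by_row.index.to_numpy(dtype=float)
    if x_rows.size < 10:
        raise ValueError("need at least 10 distinct AP positions to fit a profile")

    data_domain = (float(x_rows.min()), float(x_rows.max()))
    if domain is None:
        domain = data_domain

    mean_spline = make_smoothing_spline(x_rows, by_row.to_numpy(dtype=float), lam=smoothing)
    noise = estimate_neighbor_noise(tables, gene, bins=noise_bins, domain=data_domain)
    ok = noise.valid
    if ok.sum() < 4:
        raise ValueError("too few valid noise bins to fit an SD profile")
    sd_spline = make_smoothing_spline(
        noise.bin_centers[ok], noise.sd[ok], lam=smoothing
    )

    grid = np.linspace(*data_domain, 4096)
    norm = float(np.max(mean_spline(grid)))
    if norm <= 0:
        raise ValueError(f"gene {gene!r}: fitted profile maximum is not positive")
    dspline = mean_spline.derivative()
    sd_floor = 0.0

    def mean_fn(x: np.ndarray) -> np.ndarray:
        return np.asarray(mean_spline(x)) / norm

    def sd_fn(x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(sd_spline(x)) / norm, sd_floor, None)

    def dmean_fn(x: np.ndarray) -> np.ndarray:
        return np.asarray(dspline(x)) / norm

    return ExpressionProfile(
        gene=gene, mean=mean_fn, sd=sd_fn, dmean=dmean_fn, domain=domain, norm=norm
    )


def build_profile_set(profiles: Sequence[ExpressionProfile]) -> ProfileSet:
    """Combine fitted profiles over the intersection of their domains."""
    lo = max(p.domain[0] for p in profiles)
    hi = min(p.domain[1] for p in profiles)
    if not lo < hi:
        raise ValueError("profiles have no common domain")
    return ProfileSet(channels=tuple(p.channel() for p in profiles), domain=(lo, hi))


def roi_restrict(profile_set: ProfileSet, roi: tuple[float, float] = (0.37, 0.47)) -> ProfileSet:
    """Condition the uniform position prior on the ROI (domain truncation)."""
    return profile_set.restrict(roi)


def acc_info_curve(
    profiles: ProfileSet,
    eta0_grid: Sequence[float],
    fractional: bool = False,
    label: str = "triplet",
) -> InfoCurve:
    """Accessible information (small-noise) as a function of readout noise eta0."""
    eta0 = np.asarray(list(eta0_grid), dtype=float)

    def evaluate(e: float) -> float:
        return info.info_small_noise(profiles, extra_noise=e, fractional=fractional).value

    nats = np.array([evaluate(e) for e in eta0])
    return InfoCurve(eta0=eta0, nats=nats, evaluate=evaluate, label=label)


def noiseless_pair_bound(
    profiles: ProfileSet,
    eta0_grid: Sequence[float],
    fractional: bool = False,
    label: str = "noiseless_pair",
) -> InfoCurve:
    """Best-case curve for a strategy lacking the downstream gene.

    Every channel's expression SD is forced to zero, so only the readout noise
    eta0 limits the information; at eta0 = 0 the value diverges and is stored
    as an ``inf`` sentinel (never interpolated through).
    """
    noiseless = profiles.noiseless()

    def evaluate(e: float) -> float:
        if e == 0:
            return math.inf
        return info.info_small_noise(noiseless, extra_noise=e, fractional=fractional).value

    eta0 = np.asarray(list(eta0_grid), dtype=float)
    nats = np.array([evaluate(e) for e in eta0])
    return InfoCurve(eta0=eta0, nats=nats, evaluate=evaluate, label=label)


def find_crossing(bound_curve: InfoCurve, triplet_curve: InfoCurve) -> CrossingResult:
    """Smallest eta0 at which the triplet curve meets or exceeds the bound.

    The grid supplies the bracket; the crossing is refined by root bisection
    on the difference of the two curves' evaluators.  Returns ``None`` fields
    when no sign change occurs on the grid.
    """
    if bound_curve.eta0.shape != triplet_curve.eta0.shape or np.any(
        bound_curve.eta0 != triplet_curve.eta0
    ):
        raise ValueError("curves must share a common eta0 grid")
    eta0 = bound_curve.eta0
    diff = triplet_curve.nats - bound_curve.nats  # -inf where the bound diverges
    above = diff >= 0
    if not above.any():
        return CrossingResult(eta0_star=None, bracket=None,
                              bound_label=bound_curve.label, triplet_label=triplet_curve.label)
    k = int(np.argmax(above))
    if k == 0:
        return CrossingResult(eta0_star=float(eta0[0]), bracket=(float(eta0[0]), float(eta0[0])),
                              bound_label=bound_curve.label, triplet_label=triplet_curve.label)

    lo, hi = float(eta0[k - 1]), float(eta0[k])

    def f(e: float) -> float:
        return triplet_curve.evaluate(e) - bound_curve.evaluate(e)

    if not np.isfinite(f(lo)):
        star = hi
    elif f(lo) == 0.0:
        star = lo
    else:
        star = float(brentq(f, lo, hi, xtol=1e-6 * hi))
    return CrossingResult(eta0_star=star, bracket=(lo, hi),
                          bound_label=bound_curve.label, triplet_label=triplet_curve.label)


def run_pipeline(
    tables: pd.DataFrame | Sequence[pd.DataFrame] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    embryo_spec: EmbryoSpec | None = None,
    n_embryos: int = 8,
) -> dict:
    """The full analysis chain on nucleus tables (or a generated replicate set).

    Returns a JSON-ready report with per-gene noise summaries, per-gene raw
    information over the ROI (bits), the triplet accessible-information curve,
    the noiseless-pair bound and the crossing point.  The run is deterministic
    given the seed (randomness enters only through embryo generation).
    """
    config = config or PipelineConfig()
    if tables is None:
        if embryo_spec is None:
            raise ValueError("provide nucleus tables or an embryo_spec")
        tables = generate_embryos(embryo_spec, n_embryos, seed)
    tables = _as_tables(tables)

    fractional = config.noise_mode == "fractional"
    profiles = {}
    noise_estimates = {}
    for gene in config.genes:
        noise_estimates[gene] = estimate_neighbor_noise(tables, gene, bins=config.noise_bins)
        profiles[gene] = fit_idealized_profile(
            tables, gene, smoothing=config.smoothing, noise_bins=config.noise_bins
        )

    full_set = build_profile_set([profiles[g] for g in config.genes])
    roi_set = roi_restrict(full_set, config.roi)
    pair_set = roi_restrict(
        build_profile_set([profiles[g] for g in config.inputs]), config.roi
    )

    per_gene_info = {
        g: info.info_small_noise(
            roi_restrict(build_profile_set([profiles[g]]), config.roi)
        )
        for g in config.genes
    }

    eta0_grid = (0.0, *config.eta0_grid)
    triplet = acc_info_curve(roi_set, eta0_grid, fractional=fractional, label="triplet")
    bound = noiseless_pair_bound(pair_set, eta0_grid, fractional=fractional)
    crossing = find_crossing(bound, triplet)

    def curve_dict(c: InfoCurve) -> dict:
        return {
            "eta0": [float(e) for e in c.eta0],
            "bits": [float(b) for b in c.bits],
            "infinite": [bool(i) for i in c.infinite],
        }

    roi_lo, roi_hi = config.roi
    report = {
        "config": {
            "inputs": list(config.inputs),
            "intermediate": config.intermediate,
            "roi": [roi_lo, roi_hi],
            "noise_bins": config.noise_bins,
            "noise_mode": config.noise_mode,
            "n_tables": len(tables),
        },
        "seed": seed,
        "noise": {
            g: {
                "median_sd_roi": float(
                    np.nanmedian(
                        np.where(
                            (noise_estimates[g].bin_centers >= roi_lo)
                            & (noise_estimates[g].bin_centers <= roi_hi)
                            & noise_estimates[g].valid,
                            noise_estimates[g].sd,
                            np.nan,
                        )
                    )
                ),
                "n_pairs_total": int(noise_estimates[g].n_pairs.sum()),
            }
            for g in config.genes
        },
        "roi_info_bits": {g: per_gene_info[g].value_bits for g in config.genes},
        "curves": {"triplet": curve_dict(triplet), "noiseless_pair": curve_dict(bound)},
        "crossing": {
            "found": crossing.found,
            "eta0_star": crossing.eta0_star,
            "bracket": list(crossing.bracket) if crossing.bracket else None,
        },
    }
    report["_artifacts"] = {
        "profiles": profiles,
        "noise_estimates": noise_estimates,
        "triplet_curve": triplet,
        "bound_curve": bound,
        "roi_profile_set": roi_set,
    }
    return report
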