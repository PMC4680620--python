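"""Shared I/O plumbing: TSV/YAML/JSON readers and writers, manifests, seeding.

Conventions: nucleus tables are tab-separated with a header row
(``nucleus_id  x_ap  dv_index  <gene>...``), '.' decimal, no quoting;
positions are normalized AP fractions in [0, 1]; configs are YAML; reports are
UTF-8 JSON with sorted keys and explicit ``"Infinity"``/``"NaN"`` string
sentinels for non-finite floats, so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import (
    EmbryoSpec,
    GeneSpec,
    GradientSpec,
    NoiseSpec,
    ReadoutSpec,
    SigmoidShape,
    StripeShape,
)

__all__ = [
    "RunManifest",
    "read_nucleus_table",
    "write_nucleus_table",
    "write_report",
    "read_report",
    "write_tsv",
    "load_config",
    "gradient_spec_from_dict",
    "readout_spec_from_dict",
    "embryo_spec_from_dict",
    "spawn_rngs",
]

RESERVED_COLUMNS = ("nucleus_id", "x_ap", "dv_index")


# ---------------------------------------------------------------------------
# Nucleus tables
# ---------------------------------------------------------------------------


def read_nucleus_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a nucleus table TSV.

    Schema violations (missing columns, non-numeric expression, duplicate
    ``(x_ap, dv_index)`` coordinates) raise ``ValueError`` with row numbers
    (1-based, counting the header as row 1).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected a nucleus-table header") from None
    missing = [c for c in RESERVED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    genes = [c for c in table.columns if c not in RESERVED_COLUMNS]
    if not genes:
        raise ValueError(f"{path}: no gene expression columns found")
    for col in ("x_ap", *genes):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna() & table[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(f"{path}: non-numeric values in column {col!r} at rows {rows}")
        if numeric.isna().any():
            rows = ", ".join(str(i + 2) for i in table.index[numeric.isna()][:5])
            raise ValueError(f"{path}: missing values in column {col!r} at rows {rows}")
        table[col] = numeric
    if not pd.api.types.is_integer_dtype(table["dv_index"]):
        raise ValueError(f"{path}: dv_index must be integer")
    if (table["x_ap"].lt(0) | table["x_ap"].gt(1)).any():
        bad = table.index[table["x_ap"].lt(0) | table["x_ap"].gt(1)][:5]
        rows = ", ".join(str(i + 2) for i in bad)
        raise ValueError(f"{path}: x_ap outside [0, 1] at rows {rows}")
    dup = table.duplicated(subset=["x_ap", "dv_index"], keep=False)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in table.index[dup][:5])
        raise ValueError(f"{path}: duplicate (x_ap, dv_index) coordinates at rows {rows}")
    if (table[genes].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return table


def write_nucleus_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a nucleus table as TSV (full float precision, round-trip exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=_repr_float)
    return path


def _repr_float(x: float) -> str:
    # shortest representation that round-trips float64 exactly
    return repr(float(x))


def write_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_repr_float)
    return path


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------


def _sanitize(obj: Any) -> Any:
    """Convert to plain JSON types; non-finite floats become string sentinels."""
    if isinstance(obj, Mapping):
        return {str(k): _sanitize(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if math.isnan(x):
            return "NaN"
        if math.isinf(x):
            return "Infinity" if x > 0 else "-Infinity"
        return float(f"{x:.12g}")  # fixed precision for reproducible diffs
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: Mapping[str, Any], path: str | Path) -> Path:
    """Serialize a report as deterministic JSON.

    Keys are sorted, floats written at 12 significant digits, NaN/infinity
    written as explicit string sentinels, and private keys (leading ``_``,
    e.g. in-memory artifacts) dropped.  Identical reports yield identical
    bytes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(_sanitize(dict(report)), sort_keys=True, indent=1, allow_nan=False)
    path.write_text(payload + "\n", encoding="utf-8")
    return path


def _restore_sentinels(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _restore_sentinels(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore_sentinels(v) for v in obj]
    if obj == "Infinity":
        return math.inf
    if obj == "-Infinity":
        return -math.inf
    if obj == "NaN":
        return math.nan
    return obj


def read_report(path: str | Path) -> dict:
    return _restore_sentinels(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Configs and manifests
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg


def gradient_spec_from_dict(d: Mapping[str, Any]) -> GradientSpec:
    return GradientSpec(
        L=float(d.get("L", 1.0)),
        c_max=float(d["c_max"]),
        sigma0=float(d["sigma0"]),
        n_cells=int(d.get("n_cells", 100)),
    )


def readout_spec_from_dict(d: Mapping[str, Any]) -> ReadoutSpec:
    return ReadoutSpec(
        eta0=float(d["eta0"]),
        gain=float(d.get("gain", 1.0)),
        shape=str(d.get("shape", "linear")),
        n_eff=float(d.get("n_eff", 1.0)),
    )


def _shape_from_dict(d: Mapping[str, Any]) -> SigmoidShape | StripeShape:
    kind = d.get("kind", "sigmoid")
    if kind == "sigmoid":
        return SigmoidShape(
            midpoint=float(d["midpoint"]),
            width=float(d["width"]),
            decreasing=bool(d["decreasing"]),
            amplitude=float(d.get("amplitude", 1.0)),
            basal=float(d.get("basal", 0.0)),
        )
    if kind == "stripes":
        return StripeShape(
            centers=tuple(float(c) for c in d["centers"]),
            widths=tuple(float(w) for w in d["widths"]),
            amplitudes=tuple(float(a) for a in d["amplitudes"]),
            basal=float(d.get("basal", 0.0)),
        )
    raise ValueError(f"unknown shape kind {kind!r}")


def embryo_spec_from_dict(d: Mapping[str, Any]) -> EmbryoSpec:
    genes = {
        name: GeneSpec(
            shape=_shape_from_dict(g["shape"]),
            noise=NoiseSpec(
                kind=g.get("noise", {}).get("kind", "constant"),
                params=dict(g.get("noise", {}).get("params", {"sd": 0.05})),
            ),
        )
        for name, g in d["genes"].items()
    }
    return EmbryoSpec(
        genes=genes,
        n_ap=int(d.get("n_ap", 200)),
        n_dv=int(d.get("n_dv", 20)),
        roi=tuple(d.get("roi", (0.37, 0.47))),
        x_range=tuple(d.get("x_range", (0.0, 1.0))),
    )


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline output directory.

    ``created`` is None by default so that two runs with equal config and seed
    are byte-identical in every output; pass a timestamp explicitly when
    wall-clock provenance matters more than reproducible diffs.
    """

    seed: int
    config_hash: str
    version: str = __version__
    outputs: list[str] = field(default_factory=list)
    created: str | None = None

    @staticmethod
    def config_digest(config: Mapping[str, Any]) -> str:
        canonical = json.dumps(_sanitize(dict(config)), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        return write_report(
            {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "version": self.version,
                "outputs": sorted(self.outputs),
                "created": self.created,
            },
            out_dir / "manifest.json",
        )


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generator streams derived from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
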