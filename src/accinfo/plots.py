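"""Optional figure output (PNG): information curves and benefit maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_information_curves(curves: dict, path: str | Path, eta0_star: float | None = None) -> Path:
    """Accessible information vs readout noise: triplet curve and noiseless-pair bound."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, style in (("triplet", "-"), ("noiseless_pair", "--")):
        c = curves[label]
        eta = np.asarray(c["eta0"], dtype=float)
        bits = np.asarray(
            [np.nan if isinstance(b, str) else b for b in c["bits"]], dtype=float
        )
        ok = np.isfinite(bits) & (eta > 0)
        ax.plot(eta[ok], bits[ok], style, label=label.replace("_", " "))
    if eta0_star is not None:
        ax.axvline(eta0_star, color="0.6", lw=0.8, label=r"$\eta_0^*$")
    ax.set_xscale("log")
    ax.set_xlabel(r"readout noise $\eta_0$")
    ax.set_ylabel(r"$I_{\mathrm{acc}}$ (bits)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_benefit_map(table: pd.DataFrame, path: str | Path) -> Path:
    """Heatmap of the accessible-information gain (bits) over (n_eff, gain),
    maximized over the other grid axes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pivot = table.pivot_table(
        index="n_eff", columns="gain", values="delta_acc_bits", aggfunc="max"
    )
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    im = ax.imshow(
        pivot.to_numpy(), origin="lower", aspect="auto", cmap="RdBu_r",
        vmin=-np.nanmax(np.abs(pivot.to_numpy())), vmax=np.nanmax(np.abs(pivot.to_numpy())),
    )
    ax.set_xticks(range(len(pivot.columns)), [f"{g:g}" for g in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{n:g}" for n in pivot.index])
    ax.set_xlabel(r"gain $\lambda$")
    ax.set_ylabel(r"$N_\mathrm{eff}$")
    fig.colorbar(im, ax=ax, label=r"$\Delta I_{\mathrm{acc}}$ (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
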