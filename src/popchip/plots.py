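"""Figure helpers: LD-decay curves per breed and the PC1/PC2 scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "popchip"  # deterministic element ids
import matplotlib.pyplot as plt

from .ld_ne import LDProfile
from .pca import PCAResult


def _save(fig, path) -> None:
    path = Path(path)
    kwargs = {}
    if path.suffix == ".svg":
        kwargs["metadata"] = {"Date": None}  # keep output byte-deterministic
    fig.savefig(path, **kwargs)


def ld_decay_plot(profiles: list[LDProfile], path: str | Path) -> None:
    """Mean r² against distance (bin midpoints), one line per breed."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for prof in profiles:
        populated = prof.bins[prof.bins["n_pairs"] > 0]
        mid = (populated["lower_mb"] + populated["upper_mb"]) / 2
        ax.plot(mid, populated["mean_r2"], label=prof.breed_label, lw=1.2)
    ax.set_xlabel("distance (Mb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    _save(fig, path)
    plt.close(fig)


def pca_scatter(result: PCAResult, path: str | Path) -> None:
    """PC1 vs PC2 coloured by breed."""
    fig, ax = plt.subplots(figsize=(6, 5))
    frame = result.to_frame()
    for breed, group in frame.groupby("breed"):
        ax.scatter(group["PC1"], group["PC2"], s=14, label=breed, alpha=0.8)
    vf = result.variance_fractions
    ax.set_xlabel(f"PC1 ({vf[0]:.1%})")
    ax.set_ylabel(f"PC2 ({vf[1]:.1%})" if len(vf) > 1 else "PC2")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    _save(fig, path)
    plt.close(fig)
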