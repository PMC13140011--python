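"""Basic figure exports: Manhattan, QQ and ternary-bias plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def manhattan(assoc_table: pd.DataFrame, path: str,
              threshold: float | None = None) -> None:
    """-log10(p) against genome position, coloured per chromosome."""
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for i, (chrom, part) in enumerate(assoc_table.groupby("chrom", sort=True)):
        x = part["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(part["pvalue"]), s=6,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append((chrom, x.mean()))
        offset = x.max() + 1
    if threshold:
        ax.axhline(-np.log10(threshold), color="red", linestyle="--", lw=0.8)
    ax.set_xticks([t for _, t in ticks])
    ax.set_xticklabels([c for c, _ in ticks], rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq(pvalues, path: str) -> None:
    """Observed vs expected -log10(p) quantiles."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    expected = (np.arange(1, len(p) + 1) - 0.5) / len(p)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(-np.log10(expected), -np.log10(p), s=6, color="steelblue")
    lim = max(-np.log10(expected).max(), -np.log10(p).max())
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected " + r"$-\log_{10}(p)$")
    ax.set_ylabel("observed " + r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ternary(bias_table: pd.DataFrame, path: str,
            balanced_radius: float = 0.2) -> None:
    """Triad fractions in the 2-simplex, coloured by dominance label."""
    t = bias_table[~bias_table["unexpressed"]]
    # project (fA, fC, fD) onto the simplex plane
    x = t["f_c"] + 0.5 * t["f_d"]
    y = np.sqrt(3) / 2 * t["f_d"]
    colors = {"A-dominant": "tab:red", "C-dominant": "tab:green",
              "D-dominant": "tab:blue", "balanced": "grey"}
    fig, ax = plt.subplots(figsize=(4, 4))
    for label, part in t.groupby("label"):
        ax.scatter(x[part.index], y[part.index], s=8,
                   color=colors.get(label, "black"), label=label)
    ax.plot([0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0], color="black", lw=0.8)
    ax.legend(fontsize=6, loc="upper right")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
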