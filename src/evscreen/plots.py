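"""QC plots: volcano of gene effects, log-count concordance scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .deconvolution import CountMatrix


def volcano_plot(results: pd.DataFrame, path, effect_cutoff: float = 2.0,
                 logp_cutoff: float = 1.5) -> None:
    """Effect size vs -log10 p, hits colored by direction."""
    fig, ax = plt.subplots(figsize=(6, 5))
    hit = results["hit"].to_numpy() if "hit" in results else np.zeros(len(results), bool)
    act = hit & (results["effect"] < 0)
    sup = hit & (results["effect"] > 0)
    ax.scatter(results["effect"][~hit], results["neg_log_p"][~hit],
               s=6, c="0.6", alpha=0.5, linewidths=0, label="other")
    ax.scatter(results["effect"][act], results["neg_log_p"][act],
               s=12, c="crimson", linewidths=0, label="activator")
    ax.scatter(results["effect"][sup], results["neg_log_p"][sup],
               s=12, c="royalblue", linewidths=0, label="suppressor")
    for x in (-effect_cutoff, effect_cutoff):
        ax.axvline(x, ls="--", lw=0.7, c="k")
    ax.axhline(logp_cutoff, ls="--", lw=0.7, c="k")
    ax.set_xlabel("effect size (log2)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)


def concordance_plot(counts: CountMatrix, sample_a: str, sample_b: str, path,
                     pseudocount: float = 0.5) -> None:
    """log2 counts of one sample against another."""
    a = np.log2(counts.counts[sample_a] + pseudocount)
    b = np.log2(counts.counts[sample_b] + pseudocount)
    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(a, b, s=4, alpha=0.3, linewidths=0)
    ax.set_xlabel(f"log2 counts, {sample_a}")
    ax.set_ylabel(f"log2 counts, {sample_b}")
    ax.set_title(f"$R^2$ = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
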