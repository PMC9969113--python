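"""Figure rendering for a completed pipeline run.

Three figures summarize a run: the consensus heatmap (rows/columns ordered by
the average-linkage dendrogram of 1 - consensus, the same ordering the
cophenetic coefficient is computed on), the cell line x tumor correlation
heatmap with subtype side annotations, and per-subtype ranked boxplots of
line-tumor correlations. Figures are a reporting convenience; the numerical
outputs are the contract.
"""

from __future__ import annotations


from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list

from .consensus import consensus_linkage


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing pipeline output: {path}")
    return path


def render_reports(run_dir: str | Path) -> list[Path]:
    """Render consensus, correlation and ranking figures for a run directory."""
    run = Path(run_dir)
    out: list[Path] = []

    consensus = pd.read_csv(_require(run / "consensus.tsv"), sep="\t", index_col=0)
    C = consensus.to_numpy()
    order = leaves_list(consensus_linkage(C))
    labels = pd.read_csv(_require(run / "labels.tsv"), sep="\t")

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(C[np.ix_(order, order)], cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks([])
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(consensus.index[order], fontsize=4)
    ax.set_title("Consensus matrix (dendrogram order)")
    fig.colorbar(im, ax=ax, label="co-clustering probability")
    path = run / "consensus_heatmap.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    out.append(path)

    corr_path = run / "corr_matrix.tsv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, sep="\t", index_col=0)
        long = pd.read_csv(_require(run / "corr.tsv"), sep="\t")
        tumor_subtype = long.drop_duplicates("tumor").set_index("tumor")["subtype"]
        tumor_order = tumor_subtype.reindex(corr.columns).sort_values().index
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(corr[tumor_order].to_numpy().T, cmap="RdBu_r", aspect="auto")
        ax.set_xlabel("cell lines")
        ax.set_ylabel("tumors (grouped by subtype)")
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title("Cell line-tumor Spearman correlation")
        fig.colorbar(im, ax=ax, label="rho")
        path = run / "correlation_heatmap.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        out.append(path)

    ranking_path = run / "ranking.tsv"
    if ranking_path.exists() and corr_path.exists():
        ranking = pd.read_csv(ranking_path, sep="\t")
        long = pd.read_csv(run / "corr.tsv", sep="\t")
        subtypes = sorted(ranking["subtype"].unique())
        fig, axes = plt.subplots(
            len(subtypes), 1, figsize=(10, 3 * len(subtypes)), squeeze=False
        )
        for ax, s in zip(axes.ravel(), subtypes):
            order = ranking.loc[ranking["subtype"] == s, "cell_line"]
            data = [
                long.loc[
                    (long["subtype"] == s) & (long["cell_line"] == cl), "rho"
                ].to_numpy()
                for cl in order
            ]
            ax.boxplot(data, tick_labels=list(order))
            ax.set_title(f"correlations to {s} tumors (median-ranked)")
            ax.tick_params(axis="x", labelrotation=90, labelsize=5)
        fig.tight_layout()
        path = run / "ranking_boxplots.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        out.append(path)

    return out
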