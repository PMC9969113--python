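"""Mapping consensus clusters to named EOC subtypes and summarizing the
mutational evidence per putative subtype.

Cluster-to-subtype mapping codifies the literature-comparison step as a
per-cluster majority vote over prior annotations: the majority subtype among
a cluster's annotated members names the cluster; ties or clusters without
annotated members stay "unassigned" (the evidence is surfaced rather than
guessed at), and no two clusters may claim the same subtype — on collision
the cluster with the higher vote fraction keeps it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
VALID_STATUSES = ("altered", "wild_type", "missing")


def load_gene_panel(path: str | Path | None = None) -> dict:
    """Load the subtype gene panel (the packaged default, or a YAML path).

    Returns ``{"characteristic": {subtype: set of genes}, "panel": [genes]}``.
    """
    if path is None:
        text = (
            resources.files("eoclines").joinpath("data/panel.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    characteristic = {k: set(v) for k, v in raw["characteristic"].items()}
    for subtype, genes in characteristic.items():
        if not genes:
            raise ValueError(f"empty characteristic gene set for {subtype}")
    return {"characteristic": characteristic, "panel": list(raw.get("panel", []))}


@dataclass
class SubtypeAssignment:
    """Per-sample cluster index and inferred subtype with vote evidence."""

    table: pd.DataFrame  # sample_id, cluster, subtype, confidence
    cluster_subtypes: dict[int, str]
    vote_tallies: dict[int, dict[str, int]]

    def subtype_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return str(row["subtype"].iloc[0])


def map_clusters_to_subtypes(
    labels: pd.Series, annotations: pd.Series | pd.DataFrame
) -> SubtypeAssignment:
    """Majority-vote mapping of cluster indices to subtype names.

    ``labels`` maps sample id -> cluster index; ``annotations`` maps sample
    id -> prior subtype (a DataFrame with ``sample_id``/``subtype`` columns
    may carry several annotation records per sample — each counts as one
    vote). The label "unknown" (or missing) abstains. Confidence is the
    winning vote fraction among a cluster's votes.
    """
    if isinstance(annotations, pd.DataFrame):
        ann = annotations[["sample_id", "subtype"]].copy()
    else:
        ann = pd.DataFrame(
            {"sample_id": annotations.index, "subtype": annotations.values}
        )
    ann = ann[ann["subtype"].notna() & (ann["subtype"] != "unknown")]
    unknown_ids = set(ann["sample_id"]) - set(labels.index)
    if unknown_ids:
        raise ValueError(
            f"annotations reference samples absent from labels: "
            f"{sorted(unknown_ids)[:5]}"
        )

    tallies: dict[int, dict[str, int]] = {}
    winners: dict[int, tuple[str, float]] = {}
    for cluster in sorted(set(labels)):
        members = set(labels.index[labels == cluster])
        votes = ann[ann["sample_id"].isin(members)]["subtype"].value_counts()
        tallies[int(cluster)] = votes.to_dict()
        if votes.empty:
            winners[int(cluster)] = (UNASSIGNED, 0.0)
            continue
        top = votes.max()
        leaders = sorted(votes[votes == top].index)
        if len(leaders) > 1:
            logger.warning(
                "cluster %s: tied vote between %s; left unassigned",
                cluster,
                leaders,
            )
            winners[int(cluster)] = (UNASSIGNED, 0.0)
        else:
            winners[int(cluster)] = (leaders[0], float(top / votes.sum()))

    # resolve collisions: one subtype may name at most one cluster
    by_subtype: dict[str, list[int]] = {}
    for cluster, (subtype, conf) in winners.items():
        if subtype != UNASSIGNED:
            by_subtype.setdefault(subtype, []).append(cluster)
    for subtype, clusters in by_subtype.items():
        if len(clusters) > 1:
            keep = max(clusters, key=lambda c: (winners[c][1], -c))
            for cluster in clusters:
                if cluster != keep:
                    logger.warning(
                        "clusters %s both voted %s; cluster %s (lower vote "
                        "fraction) left unassigned",
                        clusters,
                        subtype,
                        cluster,
                    )
                    winners[cluster] = (UNASSIGNED, 0.0)

    table = pd.DataFrame(
        {
            "sample_id": labels.index,
            "cluster": labels.values,
            "subtype": [winners[int(c)][0] for c in labels.values],
            "confidence": [winners[int(c)][1] for c in labels.values],
        }
    )
    return SubtypeAssignment(
        table=table,
        cluster_subtypes={c: s for c, (s, _) in winners.items()},
        vote_tallies=tallies,
    )


def _validate_mutations(mutations: pd.DataFrame) -> pd.DataFrame:
    required = {"cell_line", "gene", "status"}
    if not required <= set(mutations.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")
    bad = set(mutations["status"]) - set(VALID_STATUSES)
    if bad:
        raise ValueError(f"invalid mutation statuses: {sorted(bad)}")
    return mutations


def alteration_frequency(
    mutations: pd.DataFrame, assignment: SubtypeAssignment
) -> pd.DataFrame:
    """Per-(subtype, gene) alteration frequency: altered / (altered + wild_type).

    Missing statuses are excluded from the denominator; a zero denominator
    yields NaN. Returns a subtype x gene DataFrame.
    """
    mutations = _validate_mutations(mutations)
    subtype_of = dict(
        zip(assignment.table["sample_id"], assignment.table["subtype"])
    )
    missing_lines = set(mutations["cell_line"]) - set(subtype_of)
    if missing_lines:
        raise ValueError(
            f"mutation table lines absent from assignment: {sorted(missing_lines)[:5]}"
        )
    df = mutations.copy()
    df["subtype"] = df["cell_line"].map(subtype_of)
    informative = df[df["status"] != "missing"]
    denom = informative.groupby(["subtype", "gene"]).size()
    altered = (
        informative[informative["status"] == "altered"]
        .groupby(["subtype", "gene"])
        .size()
    )
    freq = (altered.reindex(denom.index, fill_value=0) / denom).unstack("gene")
    # genes that are missing everywhere in some subtype become NaN columns
    all_pairs = df.groupby(["subtype", "gene"]).size().unstack("gene")
    return freq.reindex(index=all_pairs.index, columns=all_pairs.columns)


def concordance_score(
    altered_genes: set[str] | list[str],
    inferred_subtype: str,
    panel: dict[str, set[str]],
) -> float:
    """Fraction of a line's altered genes in its subtype's characteristic set.

    Returns NaN when no alterations were observed (no evidence either way).
    """
    if inferred_subtype not in panel:
        raise KeyError(f"subtype {inferred_subtype!r} not in gene panel")
    altered = set(altered_genes)
    if not altered:
        return float("nan")
    return len(altered & panel[inferred_subtype]) / len(altered)


def concordance_table(
    mutations: pd.DataFrame,
    assignment: SubtypeAssignment,
    panel: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Concordance score per cell line with an inferred (non-unassigned) subtype."""
    if panel is None:
        panel = load_gene_panel()["characteristic"]
    mutations = _validate_mutations(mutations)
    rows = []
    for _, rec in assignment.table.iterrows():
        if rec["subtype"] == UNASSIGNED or rec["subtype"] not in panel:
            continue
        line = rec["sample_id"]
        altered = set(
            mutations.loc[
                (mutations["cell_line"] == line)
                & (mutations["status"] == "altered"),
                "gene",
            ]
        )
        rows.append(
            {
                "cell_line": line,
                "subtype": rec["subtype"],
                "n_altered": len(altered),
                "concordance": concordance_score(altered, rec["subtype"], panel),
            }
        )
    return pd.DataFrame(rows)
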