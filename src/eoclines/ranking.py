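"""Cell line-tumor transcriptomic similarity: Spearman correlation matrix,
per-subtype suitability rankings, ranking comparison, and the recommendation
rule engine.

Correlations are computed on the harmonized gene set (the most-variable genes
identified in the cell lines) between every cell line and every tumor; a
line's suitability for a tumor subtype is summarized by the median (or mean)
of its correlations to that subtype's tumors, and lines are ranked in
decreasing order of that statistic. The rule engine turns the rankings into
one primary recommendation flag per line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RecommendationRules
from .subtyping import UNASSIGNED, SubtypeAssignment

logger = logging.getLogger(__name__)


def spearman_matrix(
    lines_expr: pd.DataFrame,
    tumors_expr: pd.DataFrame,
    gene_set: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every cell line against every tumor.

    Both matrices are genes x samples; they are restricted to ``gene_set``
    (default: the intersection of their gene ids) in a common order. Ranks
    use average tie handling; a zero-variance profile yields NaN correlations
    with a warning. Returns a cell-lines x tumors DataFrame.
    """
    if gene_set is None:
        gene_set = [g for g in lines_expr.index if g in set(tumors_expr.index)]
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise ValueError(f"gene set has {len(gene_set)} genes; need at least 3")
    missing = (set(gene_set) - set(lines_expr.index)) | (
        set(gene_set) - set(tumors_expr.index)
    )
    if missing:
        raise ValueError(f"genes absent from expression: {sorted(missing)[:5]}")
    L = lines_expr.loc[gene_set].to_numpy(dtype=float)
    T = tumors_expr.loc[gene_set].to_numpy(dtype=float)

    def rank_columns(M: np.ndarray) -> np.ndarray:
        R = np.apply_along_axis(stats.rankdata, 0, M)
        sd = R.std(axis=0)
        return R, sd

    RL, sd_l = rank_columns(L)
    RT, sd_t = rank_columns(T)
    flat = np.concatenate([np.flatnonzero(sd_l == 0), np.flatnonzero(sd_t == 0)])
    if flat.size:
        warnings.warn(
            "zero-variance profile(s) detected; their correlations are NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    RL = (RL - RL.mean(axis=0)) / np.where(sd_l == 0, np.nan, sd_l)
    RT = (RT - RT.mean(axis=0)) / np.where(sd_t == 0, np.nan, sd_t)
    corr = (RL.T @ RT) / len(gene_set)
    return pd.DataFrame(corr, index=lines_expr.columns, columns=tumors_expr.columns)


@dataclass
class SuitabilityRanking:
    """Ordered cell lines for one tumor subtype."""

    subtype: str
    statistic: str
    table: pd.DataFrame  # cell_line, value, rank (1 = most similar)

    @property
    def ordered_lines(self) -> list[str]:
        return list(self.table["cell_line"])


def rank_by_correlation(
    corr: pd.DataFrame,
    tumor_subtypes: pd.Series,
    subtype: str,
    statistic: str = "median",
) -> SuitabilityRanking:
    """Rank cell lines by median (or mean) correlation to a subtype's tumors.

    Descending order; ties are broken lexicographically by cell-line id with
    a logged note.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    tumor_subtypes = tumor_subtypes.reindex(corr.columns)
    cols = list(corr.columns[tumor_subtypes == subtype])
    if not cols:
        raise ValueError(f"no tumors of subtype {subtype!r}")
    sub = corr[cols]
    values = sub.median(axis=1) if statistic == "median" else sub.mean(axis=1)
    if values.duplicated().any():
        logger.info(
            "ties in %s correlation for subtype %s broken lexicographically",
            statistic,
            subtype,
        )
    order = sorted(values.index, key=lambda cl: (-values[cl], cl))
    table = pd.DataFrame(
        {
            "cell_line": order,
            "value": [values[cl] for cl in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return SuitabilityRanking(subtype=subtype, statistic=statistic, table=table)


def compare_rankings(
    rank_a: SuitabilityRanking | list[str], rank_b: SuitabilityRanking | list[str]
) -> tuple[float, float]:
    """Spearman rho (and two-sided p) between two suitability rankings.

    The comparison is restricted to items present in both rankings; at least
    5 common items are required. The p-value uses the t approximation.
    """
    a = rank_a.ordered_lines if isinstance(rank_a, SuitabilityRanking) else list(rank_a)
    b = rank_b.ordered_lines if isinstance(rank_b, SuitabilityRanking) else list(rank_b)
    common = [x for x in a if x in set(b)]
    if len(common) < 5:
        raise ValueError(f"only {len(common)} common items; need at least 5")
    pos_a = {x: i for i, x in enumerate(x for x in a if x in set(common))}
    pos_b = {x: i for i, x in enumerate(x for x in b if x in set(common))}
    ra = [pos_a[x] for x in common]
    rb = [pos_b[x] for x in common]
    rho, p = stats.spearmanr(ra, rb)
    return float(rho), float(p)


#: primary recommendation flags
FLAG_RECOMMENDED = "recommended"
FLAG_AVOID = "avoid"
FLAG_AMBIGUOUS = "ambiguous"
FLAG_POTENTIAL = "potential"  # potential model of the tumor-less subtype


def recommend_lines(
    corr: pd.DataFrame,
    assignment: SubtypeAssignment,
    tumor_subtypes: pd.Series,
    rules: RecommendationRules | None = None,
) -> pd.DataFrame:
    """Apply the recommendation rule engine to the correlation matrix.

    Every line receives exactly one primary flag, with precedence
    avoid(i) > avoid(ii) > ambiguous(iii) > potential(iv) > recommended;
    all triggering rule ids are recorded. See
    :class:`eoclines.config.RecommendationRules` for the rule definitions.
    """
    rules = rules or RecommendationRules()
    rules.validate()
    subtype_of = dict(zip(assignment.table["sample_id"], assignment.table["subtype"]))
    missing = set(corr.index) - set(subtype_of)
    if missing:
        raise ValueError(f"assignment lacks lines: {sorted(missing)[:5]}")

    tumor_subtypes = tumor_subtypes.reindex(corr.columns)
    observed = sorted(set(tumor_subtypes.dropna()))
    rankings = {
        s: rank_by_correlation(corr, tumor_subtypes, s, "median") for s in observed
    }
    rank_pos = {
        s: dict(zip(r.table["cell_line"], r.table["rank"])) for s, r in rankings.items()
    }
    medians = pd.DataFrame(
        {
            s: rankings[s].table.set_index("cell_line")["value"]
            for s in observed
        }
    ).reindex(corr.index)
    overall_median = corr.median(axis=1)
    cutoff = overall_median.quantile(rules.q_low)

    rows = []
    for line in corr.index:
        assigned = subtype_of[line]
        triggered: list[str] = []
        if overall_median[line] < cutoff:
            triggered.append("i")
        if assigned in observed and rank_pos[assigned][line] > rules.top_n:
            triggered.append("ii")
        n_top = sum(1 for s in observed if rank_pos[s][line] <= rules.top_k)
        if n_top >= rules.multi_subtypes:
            triggered.append("iii")
        tumorless = assigned not in observed and assigned != UNASSIGNED
        if tumorless and "iii" not in triggered:
            triggered.append("iv")

        if "i" in triggered or "ii" in triggered:
            flag = FLAG_AVOID
        elif "iii" in triggered:
            flag = FLAG_AMBIGUOUS
        elif "iv" in triggered:
            flag = FLAG_POTENTIAL
        else:
            flag = FLAG_RECOMMENDED
        row = {
            "cell_line": line,
            "subtype": assigned,
            "overall_median": float(overall_median[line]),
            "flag": flag,
            "recommended_for": assigned if flag == FLAG_RECOMMENDED else "",
            "rules": ",".join(triggered),
        }
        for s in observed:
            row[f"median_{s}"] = float(medians.loc[line, s])
        rows.append(row)
    return pd.DataFrame(rows)
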