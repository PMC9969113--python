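"""Multi-restart NMF consensus clustering, quality metrics and rank selection.

The consensus matrix over n independent NMF restarts is the entry-wise mean
of their binary connectivity matrices; its entries estimate the probability
that two samples co-cluster. Cluster robustness at a candidate rank r is
summarized by

- the cophenetic correlation coefficient: Pearson correlation between the
  consensus-derived distances d = 1 - C and the cophenetic distances of the
  average-linkage dendrogram built on d;
- the dispersion (1/m^2) sum 4 (c_ij - 1/2)^2, which is 1 for a perfectly
  binary consensus and approaches 0 for a scattered one;
- silhouette scores on the distance 1 - C.

The factorization rank is chosen by surveying ranks on the original data and
on a column-permuted copy: the first rank where the original data's RSS
decrease falls below the permuted data's marks overfitting, and among the
ranks below it the one with maximal cophenetic coefficient is selected (ties
toward the larger rank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples
from sklearn.utils.validation import check_array

from .nmf import Factorization, assign_clusters, derive_seed, factorize, permute_matrix

logger = logging.getLogger(__name__)


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary samples x samples matrix: 1 iff two samples share a label."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D array")
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(connectivities: list[np.ndarray]) -> np.ndarray:
    """Entry-wise mean of connectivity matrices (symmetric, unit diagonal)."""
    if not connectivities:
        raise ValueError("need at least one connectivity matrix")
    shapes = {c.shape for c in connectivities}
    if len(shapes) != 1:
        raise ValueError(f"connectivity shapes differ: {shapes}")
    return np.mean(connectivities, axis=0)


def _check_consensus(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    if not np.allclose(C, C.T):
        raise ValueError("consensus must be symmetric")
    if C.min() < -1e-12 or C.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0, 1]")
    return np.clip(C, 0.0, 1.0)


def consensus_linkage(C: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering of the distance 1 - C."""
    C = _check_consensus(C)
    d = squareform(1.0 - C, checks=False)
    return average(d)


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Correlation between consensus distances and dendrogram cophenetic ones.

    Average-linkage clustering is run on d = 1 - C; the coefficient is the
    Pearson correlation between the upper-triangle entries of d and the
    corresponding cophenetic distances. A degenerate case where d is constant
    (e.g. a single perfect block) is reproduced exactly by the dendrogram and
    scored 1 by convention.
    """
    C = _check_consensus(C)
    if C.shape[0] < 3:
        raise ValueError("cophenetic coefficient needs at least 3 samples")
    d = squareform(1.0 - C, checks=False)
    Z = average(d)
    coph_dists = cophenet(Z)
    if np.ptp(d) == 0 or np.ptp(coph_dists) == 0:
        return 1.0 if np.allclose(d, coph_dists) else 0.0
    return float(np.corrcoef(d, coph_dists)[0, 1])


def dispersion(C: np.ndarray) -> float:
    """(1/m^2) sum 4 (c_ij - 1/2)^2: 1 for a binary consensus, -> 0 scattered."""
    C = _check_consensus(C)
    return float(np.mean(4.0 * (C - 0.5) ** 2))


def hierarchical_labels(C: np.ndarray, r: int) -> np.ndarray:
    """Cut the average-linkage consensus dendrogram into r clusters (1-based)."""
    Z = consensus_linkage(C)
    return fcluster(Z, t=r, criterion="maxclust")


def consensus_silhouettes(C: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette score per sample on the distance 1 - C.

    s = (b - a) / max(a, b) with a the mean intra-cluster distance and b the
    minimum over other clusters of the mean distance; samples in singleton
    clusters score 0 by convention (as sklearn's silhouette does).
    """
    C = _check_consensus(C)
    labels = np.asarray(labels)
    if labels.shape[0] != C.shape[0]:
        raise ValueError("labels must match consensus dimension")
    if np.unique(labels).size < 2:
        raise ValueError("silhouettes need at least 2 clusters")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return silhouette_samples(D, labels, metric="precomputed")


@dataclass
class ConsensusResult:
    """Consensus matrix over restarts with quality metrics and labels.

    ``labels`` come from the best-objective restart's H via maximum
    coefficient (the subtype-call labels); ``hclust_labels`` cut the
    consensus dendrogram at r (the labels silhouettes are computed on,
    mirroring the consensus-map dendrogram).
    """

    consensus: np.ndarray
    cophenetic: float
    dispersion: float
    silhouettes: np.ndarray
    labels: np.ndarray
    hclust_labels: np.ndarray
    n_runs: int
    r: int
    best: Factorization
    rss_best: float


def run_consensus(
    V: np.ndarray,
    r: int,
    n_runs: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    objective: str = "kl",
) -> ConsensusResult:
    """Consensus clustering over ``n_runs`` independent NMF restarts.

    Restart seeds are derived deterministically from the master seed, so the
    whole result is reproducible. Metrics (cophenetic, dispersion,
    silhouettes) are computed on the consensus matrix.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    connectivities = []
    best: Factorization | None = None
    for i in range(n_runs):
        fact = factorize(
            V,
            r,
            seed=derive_seed(seed, i),
            max_iter=max_iter,
            tol=tol,
            objective=objective,
        )
        connectivities.append(connectivity_matrix(assign_clusters(fact.H)))
        if best is None or fact.final_objective < best.final_objective:
            best = fact
    assert best is not None
    C = consensus_matrix(connectivities)
    hlabels = hierarchical_labels(C, r)
    if np.unique(hlabels).size >= 2:
        sil = consensus_silhouettes(C, hlabels)
    else:
        sil = np.zeros(C.shape[0])
    return ConsensusResult(
        consensus=C,
        cophenetic=cophenetic_coefficient(C),
        dispersion=dispersion(C),
        silhouettes=sil,
        labels=assign_clusters(best.H),
        hclust_labels=hlabels,
        n_runs=n_runs,
        r=r,
        best=best,
        rss_best=best.rss,
    )


@dataclass
class RankSurveyResult:
    """Per-rank metrics on original and column-permuted data."""

    table: pd.DataFrame  # columns: rank, data, cophenetic, dispersion,
    #                      mean_silhouette, rss
    ranks: list[int]

    def metric(self, name: str, data: str) -> pd.Series:
        sub = self.table[self.table["data"] == data].set_index("rank")
        return sub[name]


def rank_survey(
    V: np.ndarray,
    ranks: list[int] | range,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    objective: str = "kl",
) -> RankSurveyResult:
    """Survey candidate ranks on V and on a column-permuted copy of V.

    For each rank, a full consensus run is performed on both matrices and
    the cophenetic coefficient, dispersion, mean silhouette and best-restart
    RSS recorded. The permuted copy (entries shuffled within each column)
    serves as the overfitting null for rank selection.
    """
    ranks = sorted(set(int(r) for r in ranks))
    if not ranks:
        raise ValueError("ranks must be non-empty")
    V = np.asarray(V, dtype=float)
    V_perm = permute_matrix(V, seed=derive_seed(seed, 999_983))
    rows = []
    for condition, data in (("original", V), ("permuted", V_perm)):
        for r in ranks:
            res = run_consensus(
                data,
                r,
                n_runs=n_runs,
                seed=derive_seed(seed, r),
                max_iter=max_iter,
                tol=tol,
                objective=objective,
            )
            rows.append(
                {
                    "rank": r,
                    "data": condition,
                    "cophenetic": res.cophenetic,
                    "dispersion": res.dispersion,
                    "mean_silhouette": float(np.mean(res.silhouettes)),
                    "rss": res.rss_best,
                }
            )
            logger.info(
                "rank survey: r=%d %s cophenetic=%.4f dispersion=%.4f rss=%.4g",
                r,
                condition,
                res.cophenetic,
                res.dispersion,
                res.rss_best,
            )
    return RankSurveyResult(table=pd.DataFrame(rows), ranks=ranks)


@dataclass
class SelectedRank:
    rank: int
    overfit_rank: int
    eligible: list[int]
    rule_tag: str


def select_rank(
    survey: RankSurveyResult | pd.DataFrame, tie_tol: float = 1e-3
) -> SelectedRank:
    """Apply the two-criterion rank-selection rule to a survey.

    The overfit rank r_o is the smallest surveyed rank whose RSS decrease on
    the original data, dRSS(r) = RSS(r-1) - RSS(r), falls below the decrease
    on permuted data (r_o = max rank + 1 if never). Among surveyed ranks
    below r_o, the rank with maximal cophenetic coefficient is selected,
    ties broken toward the larger rank. Cophenetic coefficients are
    finite-restart Monte-Carlo estimates, so values within ``tie_tol`` of
    the maximum count as tied.
    """
    table = survey.table if isinstance(survey, RankSurveyResult) else survey
    orig = table[table["data"] == "original"].set_index("rank").sort_index()
    perm = table[table["data"] == "permuted"].set_index("rank").sort_index()
    ranks = list(orig.index)
    if len(ranks) < 3 or ranks != list(perm.index):
        raise ValueError("survey must cover >= 3 consecutive ranks on both conditions")
    d_orig = -orig["rss"].diff()
    d_perm = -perm["rss"].diff()
    overfit = [r for r in ranks[1:] if d_orig[r] < d_perm[r]]
    r_o = overfit[0] if overfit else max(ranks) + 1
    eligible = [r for r in ranks if r < r_o]
    if not eligible:
        raise ValueError(
            f"no eligible rank below the overfit rank {r_o}; survey:\n{table}"
        )
    coph = orig.loc[eligible, "cophenetic"]
    best = max(r for r in eligible if coph[r] >= coph.max() - tie_tol)
    tag = (
        f"max-cophenetic among ranks < overfit rank {r_o} "
        f"(dRSS_original < dRSS_permuted rule)"
    )
    logger.info("selected rank %d (overfit at %s, eligible %s)", best, r_o, eligible)
    return SelectedRank(rank=best, overfit_rank=r_o, eligible=eligible, rule_tag=tag)


class NMFConsensusClusterer(ClusterMixin, BaseEstimator):
    """scikit-learn-style consensus clustering estimator.

    X is samples x features; fitting runs ``n_runs`` NMF restarts on X.T and
    exposes the consensus matrix and quality metrics as fitted attributes.
    ``labels_`` are 1-based maximum-coefficient assignments from the
    best-objective restart.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        n_runs: int = 50,
        max_iter: int = 2000,
        tol: float = 1e-6,
        objective: str = "kl",
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.objective = objective
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        result = run_consensus(
            X.T,
            self.n_clusters,
            n_runs=self.n_runs,
            seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
            objective=self.objective,
        )
        self.result_ = result
        self.consensus_ = result.consensus
        self.labels_ = result.labels
        self.hclust_labels_ = result.hclust_labels
        self.cophenetic_ = result.cophenetic
        self.dispersion_ = result.dispersion
        self.silhouettes_ = result.silhouettes
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
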