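"""Subtype-structured negative-binomial count simulator.

Generates cell-line and tumor count matrices with planted histological
subtypes, batch effects and (for tumors) purity dilution, so that every
downstream stage — variance stabilization, MAD filtering, NMF consensus
clustering, subtype mapping and correlation ranking — can be exercised and
validated without any external download.

The generative model, per sample s of subtype c with library size L_s:

    relative profile  p_g = f_s * sig_g(c) + (1 - f_s) * baseline_g
    expected counts   mu_gs = L_s * p_g / sum_g p_g
    observed counts   ~ NegativeBinomial(mean mu_gs, variance mu + alpha mu^2)

where f_s is 1 for a faithful cell line, the tumor purity for tumors, or a
graded "fidelity" dial used to plant known orderings of line-to-subtype
similarity. Batch effects shift and scale expected means on the log scale
relative to the first batch before counts are drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .config import SimulationConfig

logger = logging.getLogger(__name__)

# stream tags for deterministic per-purpose RNG derivation
_TAG_SIGNATURES = 1
_TAG_LINES = 2
_TAG_TUMORS = 3
_TAG_BATCH = 4
_TAG_ANNOT = 5
_TAG_DIVERGENT = 6
_TAG_DRAW = 100


def _rng(*entropy: int) -> np.random.Generator:
    """Derive an independent, reproducible stream from integer entropy."""
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SubtypeSignatureSet:
    """Per-subtype expected relative expression profiles.

    ``signatures`` is a (genes x k) non-negative matrix of relative expression
    levels (2**log2-offsets over the baseline); ``signature_gene_index`` maps
    each subtype to its disjoint set of planted upregulated genes; ``baseline``
    is the per-gene baseline log2 level shared by non-signature genes.
    """

    genes: list[str]
    subtypes: tuple[str, ...]
    signatures: np.ndarray
    signature_gene_index: dict[str, set[str]]
    baseline: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.signatures < 0):
            raise ValueError("signature values must be non-negative")
        if len(self.subtypes) < 2:
            raise ValueError("need at least two subtypes")
        sets = list(self.signature_gene_index.values())
        if sets and sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("signature gene sets must be disjoint")

    @property
    def baseline_relative(self) -> np.ndarray:
        return np.exp2(self.baseline)


@dataclass
class LabeledCountMatrix:
    """A count matrix plus metadata carrying the planted truth.

    ``counts`` is genes x samples (integer DataFrame); ``metadata`` has one
    row per sample (sample_id, kind, batch, true_subtype, purity/fidelity,
    prior_subtype). ``means`` holds the expected count means the counts were
    drawn from, and ``draw_seeds`` the per-sample entropy used for the draw,
    so batch perturbation can redraw reproducibly.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    means: np.ndarray
    draw_seeds: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.metadata["sample_id"]):
            raise ValueError("metadata rows must match count columns one-to-one")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


def generate_signatures(config: SimulationConfig) -> SubtypeSignatureSet:
    """Plant disjoint signature gene sets with log2 fold-change structure.

    Each subtype receives ``n_sig_genes_per_subtype`` genes upregulated by
    N(logfc_mean, logfc_sd) in that subtype; the same genes vary across the
    remaining subtypes with N(0, cross_logfc_ratio * logfc_mean) offsets so
    that marker genes are graded across subtypes rather than binary on/off.
    Non-signature genes sit exactly on the baseline in every subtype.
    Signature-gene baselines are drawn from the lower end of the expression
    range (lineage-restricted markers), so upregulation in the own subtype
    creates strong multiplicative contrast.
    """
    config.validate()
    k = config.k_subtypes
    rng = _rng(config.rng_seed, _TAG_SIGNATURES)
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes
    )

    order = rng.permutation(config.n_genes)
    offsets = np.zeros((config.n_genes, k))
    index: dict[str, set[str]] = {}
    cross_sd = config.cross_logfc_ratio * abs(config.logfc_mean)
    pos = 0
    for ci, subtype in enumerate(config.subtype_names):
        sel = order[pos : pos + config.n_sig_genes_per_subtype]
        pos += config.n_sig_genes_per_subtype
        index[subtype] = {genes[g] for g in sel}
        baseline[sel] = rng.normal(
            config.sig_baseline_log2_mean,
            config.sig_baseline_log2_sd,
            size=sel.size,
        )
        own = rng.normal(config.logfc_mean, config.logfc_sd, size=sel.size)
        cross = rng.normal(0.0, cross_sd, size=(sel.size, k))
        offsets[sel, :] = cross
        offsets[sel, ci] = own
    signatures = np.exp2(baseline[:, None] + offsets)
    return SubtypeSignatureSet(
        genes=genes,
        subtypes=config.subtype_names,
        signatures=signatures,
        signature_gene_index=index,
        baseline=baseline,
    )


def _draw_counts(
    mean: np.ndarray, dispersion: float, entropy: tuple[int, ...]
) -> np.ndarray:
    """Draw one sample's counts from NB(mean, var = mu + alpha mu^2)."""
    rng = _rng(*entropy)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _expected_means(
    signatures: SubtypeSignatureSet,
    subtype_idx: np.ndarray,
    fidelity: np.ndarray,
    library: np.ndarray,
) -> np.ndarray:
    base = signatures.baseline_relative
    profiles = (
        fidelity[None, :] * signatures.signatures[:, subtype_idx]
        + (1.0 - fidelity)[None, :] * base[:, None]
    )
    profiles = profiles / profiles.sum(axis=0, keepdims=True)
    return profiles * library[None, :]


def _annotate(
    truth: Sequence[str], fraction: float, rng: np.random.Generator
) -> list[str]:
    keep = rng.random(len(truth)) < fraction
    return [t if k else "unknown" for t, k in zip(truth, keep)]


def simulate_cell_lines(
    signatures: SubtypeSignatureSet,
    config: SimulationConfig,
    fidelity: Sequence[float] | None = None,
) -> LabeledCountMatrix:
    """Simulate the cell-line panel (balanced subtypes, round-robin batches).

    ``fidelity`` optionally dials each line's similarity to its planted
    subtype (1 = pure subtype profile, 0 = pure baseline); default all 1.
    """
    n = config.n_cell_lines
    rng = _rng(config.rng_seed, _TAG_LINES)
    subtype_idx = np.arange(n) % config.k_subtypes
    library = np.exp(
        rng.normal(config.library_size_logmean, config.library_size_logsd, size=n)
    )
    if np.any(library <= 0):
        raise ValueError("library sizes must be positive")
    if fidelity is None:
        fid = np.ones(n)
    else:
        fid = np.asarray(fidelity, dtype=float)
        if fid.shape != (n,):
            raise ValueError(f"fidelity must have length {n}")
        if np.any((fid < 0) | (fid > 1)):
            raise ValueError("fidelity values must lie in [0, 1]")
    means = _expected_means(signatures, subtype_idx, fid, library)

    ids = [f"CL{i + 1:03d}" for i in range(n)]
    truth = [config.subtype_names[c] for c in subtype_idx]
    draw_seeds = [(config.rng_seed, _TAG_LINES, _TAG_DRAW + i) for i in range(n)]
    counts = np.column_stack(
        [
            _draw_counts(means[:, i], config.nb_dispersion, draw_seeds[i])
            for i in range(n)
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "kind": "cell_line",
            "batch": [f"CLB{i % config.n_batches_cell_lines + 1}" for i in range(n)],
            "true_subtype": truth,
            "purity": np.nan,
            "fidelity": fid,
            "prior_subtype": _annotate(
                truth, config.annotation_fraction, _rng(config.rng_seed, _TAG_ANNOT)
            ),
        }
    )
    return LabeledCountMatrix(
        counts=pd.DataFrame(counts, index=signatures.genes, columns=ids),
        metadata=meta,
        means=means,
        draw_seeds=draw_seeds,
    )


def simulate_tumors(
    signatures: SubtypeSignatureSet, config: SimulationConfig
) -> LabeledCountMatrix:
    """Simulate tumors with purity dilution toward the stromal baseline.

    Purity is Uniform(purity_low, purity_high) per tumor; the stromal profile
    is the global baseline (no separate stromal signature by default). The
    subtype split follows ``n_tumors_per_subtype``.
    """
    config.validate()
    name_to_idx = {s: i for i, s in enumerate(config.subtype_names)}
    subtype_idx = np.concatenate(
        [
            np.full(n, name_to_idx[s], dtype=int)
            for s, n in zip(config.tumor_subtypes, config.n_tumors_per_subtype)
        ]
    )
    n = subtype_idx.size
    rng = _rng(config.rng_seed, _TAG_TUMORS)
    library = np.exp(
        rng.normal(config.library_size_logmean, config.library_size_logsd, size=n)
    )
    purity = rng.uniform(config.purity_low, config.purity_high, size=n)
    means = _expected_means(signatures, subtype_idx, purity, library)

    ids = [f"T{i + 1:03d}" for i in range(n)]
    truth = [config.subtype_names[c] for c in subtype_idx]
    draw_seeds = [(config.rng_seed, _TAG_TUMORS, _TAG_DRAW + i) for i in range(n)]
    counts = np.column_stack(
        [
            _draw_counts(means[:, i], config.nb_dispersion, draw_seeds[i])
            for i in range(n)
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "kind": "tumor",
            "batch": [f"TB{i % config.n_batches_tumors + 1}" for i in range(n)],
            "true_subtype": truth,
            "purity": purity,
            "fidelity": np.nan,
            "prior_subtype": truth,  # tumors are histologically assessed
        }
    )
    return LabeledCountMatrix(
        counts=pd.DataFrame(counts, index=signatures.genes, columns=ids),
        metadata=meta,
        means=means,
        draw_seeds=draw_seeds,
    )


def apply_batch_effects(
    data: LabeledCountMatrix, config: SimulationConfig
) -> LabeledCountMatrix:
    """Perturb expected means with per-batch location/scale effects and redraw.

    Batches are taken from ``data.metadata['batch']``. For every batch after
    the first (the reference), each gene receives a natural-log location shift
    N(0, batch_location_sd) and a log-scale factor exp(N(0, batch_scale_sd))
    applied to the gene's log-mean deviation from its grand log-mean. Counts
    are redrawn from the shifted means with the original per-sample seeds, so
    zero-magnitude effects reproduce the input exactly. Truth is unchanged.
    """
    if "batch" not in data.metadata.columns or data.metadata["batch"].isna().any():
        raise ValueError("every sample must carry a batch label")
    batches = data.metadata["batch"].to_numpy()
    batch_order = list(dict.fromkeys(batches))  # first occurrence = reference
    log_mu = np.log(data.means)
    grand = log_mu.mean(axis=1, keepdims=True)
    adjusted = log_mu.copy()
    for bi, batch in enumerate(batch_order[1:], start=1):
        brng = _rng(config.rng_seed, _TAG_BATCH, bi)
        delta = brng.normal(0.0, config.batch_location_sd, size=log_mu.shape[0])
        scale = np.exp(brng.normal(0.0, config.batch_scale_sd, size=log_mu.shape[0]))
        cols = np.flatnonzero(batches == batch)
        adjusted[:, cols] = (
            grand + (log_mu[:, cols] - grand) * scale[:, None] + delta[:, None]
        )
    means = np.exp(adjusted)
    counts = np.column_stack(
        [
            _draw_counts(means[:, i], config.nb_dispersion, data.draw_seeds[i])
            for i in range(means.shape[1])
        ]
    )
    return LabeledCountMatrix(
        counts=pd.DataFrame(
            counts, index=data.counts.index, columns=data.counts.columns
        ),
        metadata=data.metadata.copy(),
        means=means,
        draw_seeds=list(data.draw_seeds),
    )


def simulate_panel(
    config: SimulationConfig, batch_effects: bool = True
) -> tuple[LabeledCountMatrix, LabeledCountMatrix]:
    """Convenience: signatures -> cell lines + tumors, with batch effects."""
    signatures = generate_signatures(config)
    lines = simulate_cell_lines(signatures, config)
    tumors = simulate_tumors(signatures, config)
    if batch_effects:
        lines = apply_batch_effects(lines, config)
        tumors = apply_batch_effects(tumors, config)
    return lines, tumors


def graded_fidelities(
    config: SimulationConfig,
    n_per_subtype: int = 6,
    low: float = 0.35,
    high: float = 1.0,
    poor_line_fidelity: float = 0.05,
) -> np.ndarray:
    """Fidelity vector planting a known similarity order per subtype.

    The first line of the panel is the planted "poor" line (near-baseline
    expression, poorly similar to every subtype); the remaining lines cycle
    through subtypes with fidelities graded from ``high`` down to ``low``.
    Requires ``config.n_cell_lines == 1 + k_subtypes * n_per_subtype``.
    """
    n = 1 + config.k_subtypes * n_per_subtype
    if config.n_cell_lines != n:
        raise ValueError(
            f"graded panel needs n_cell_lines = {n}, got {config.n_cell_lines}"
        )
    grades = np.linspace(high, low, n_per_subtype)
    fid = np.empty(n)
    fid[0] = poor_line_fidelity
    # lines cycle subtypes (index i -> subtype (i % k)); line 0 has subtype 0
    for i in range(1, n):
        rank = (i - 1) // config.k_subtypes
        fid[i] = grades[rank]
    return fid


def make_divergent(
    data: LabeledCountMatrix,
    config: SimulationConfig,
    line_index: int = 0,
    divergent_sd: float = 3.0,
) -> LabeledCountMatrix:
    """Replace one line's profile with a private, divergent expression program.

    The line's expected expression becomes the baseline plus per-gene log2
    offsets N(0, divergent_sd) private to this line — the analogue of a cell
    line whose transcriptome resembles no tumor subtype (the kind of model
    the recommendation rules flag as "poor correlation to tumors overall").
    Counts are redrawn for that line only; its fidelity is recorded as 0.
    """
    rng = _rng(config.rng_seed, _TAG_DIVERGENT, line_index)
    log2_base = np.log2(data.means[:, line_index])
    rel = np.exp2(
        log2_base - log2_base.mean()
        + rng.normal(0.0, divergent_sd, size=data.means.shape[0])
    )
    library = data.means[:, line_index].sum()
    means = data.means.copy()
    means[:, line_index] = rel / rel.sum() * library
    counts = data.counts.copy()
    counts.iloc[:, line_index] = _draw_counts(
        means[:, line_index], config.nb_dispersion, data.draw_seeds[line_index]
    )
    metadata = data.metadata.copy()
    metadata.loc[metadata.index[line_index], "fidelity"] = 0.0
    return LabeledCountMatrix(
        counts=counts, metadata=metadata, means=means,
        draw_seeds=list(data.draw_seeds),
    )


def simulate_suitability_panel(
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_per_subtype: int = 6,
    low: float = 0.35,
    high: float = 1.0,
) -> tuple[LabeledCountMatrix, LabeledCountMatrix]:
    """Build the graded-similarity study panel: a known suitability ordering.

    Four tumor-matched subtypes; per subtype, ``n_per_subtype`` cell lines
    with fidelities graded from ``high`` to ``low`` (the planted suitability
    order), plus one divergent "poor" line resembling no subtype. Tumors are
    near-pure and batch effects are off: the study isolates the planted
    similarity axis from the purity and batch confounders, which have their
    own dedicated checks.
    """
    if config is None:
        config = SimulationConfig(
            k_subtypes=4,
            subtype_names=("HGSOC", "CCOC", "ENOC", "MOC"),
            tumor_subtypes=("HGSOC", "CCOC", "ENOC", "MOC"),
            n_tumors_per_subtype=(64, 16, 8, 5),
            n_cell_lines=1 + 4 * n_per_subtype,
            purity_low=0.85,
            purity_high=1.0,
            batch_location_sd=0.0,
            batch_scale_sd=0.0,
            rng_seed=seed,
        )
    signatures = generate_signatures(config)
    fidelity = graded_fidelities(config, n_per_subtype=n_per_subtype,
                                 low=low, high=high)
    lines = simulate_cell_lines(signatures, config, fidelity=fidelity)
    lines = make_divergent(lines, config, line_index=0)
    tumors = simulate_tumors(signatures, config)
    return lines, tumors


def write_fixture(data: LabeledCountMatrix, path: str | Path) -> dict[str, Path]:
    """Write counts (TSV + MatrixMarket with sidecars), metadata and truth.

    Emits ``counts.tsv`` (genes x samples, first column ``gene_id``),
    ``counts.mtx`` + ``genes.txt`` + ``samples.txt``, ``metadata.tsv`` and
    ``truth.tsv``. Round-trips losslessly through :func:`eoclines.io.read_counts`.
    """
    out = Path(path)
    try:
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "counts_tsv": out / "counts.tsv",
            "counts_mtx": out / "counts.mtx",
            "genes": out / "genes.txt",
            "samples": out / "samples.txt",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.tsv",
        }
        data.counts.rename_axis("gene_id").to_csv(files["counts_tsv"], sep="\t")
        scipy.io.mmwrite(
            files["counts_mtx"],
            scipy.sparse.coo_matrix(data.counts.values),
            field="integer",
        )
        files["genes"].write_text("\n".join(data.counts.index) + "\n")
        files["samples"].write_text("\n".join(data.counts.columns) + "\n")
        meta_cols = ["sample_id", "kind", "batch", "prior_subtype"]
        data.metadata[meta_cols].to_csv(files["metadata"], sep="\t", index=False)
        truth_cols = ["sample_id", "true_subtype", "purity", "fidelity"]
        data.metadata[truth_cols].to_csv(files["truth"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc
    return files
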