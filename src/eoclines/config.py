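"""Configuration objects for the synthetic-data generator and the rule engine.

All configuration is plain dataclasses serializable to/from YAML so that a run
is fully reproducible from its config file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Canonical names of the five major EOC histological subtypes.
EOC_SUBTYPES = ("HGSOC", "CCOC", "ENOC", "MOC", "LGSOC")

#: Subtypes with primary-tumor RNA-seq available; LGSOC has none.
TUMOR_SUBTYPES = ("HGSOC", "CCOC", "ENOC", "MOC")


@dataclass
class SimulationConfig:
    """Parameters of the negative-binomial subtype-structured count simulator.

    The defaults mirror the study design the package emulates: 56 cell lines
    from 3 source batches with 5 latent subtypes, and 93 tumors (64 HGSOC,
    16 CCOC, 8 ENOC, 5 MOC) from 3 further source batches. Effect sizes are
    log2-scale fold changes of subtype signature genes over a shared baseline.

    Parameters
    ----------
    n_genes:
        Total number of genes simulated. Desk-scale default (2000) rather than
        transcriptome-scale; signature structure is what matters downstream.
    k_subtypes:
        Number of latent subtypes planted in the cell-line panel.
    n_cell_lines, n_tumors_per_subtype:
        Panel sizes. Tumor counts are per entry of ``tumor_subtypes``.
    n_sig_genes_per_subtype:
        Size of each subtype's disjoint signature gene set.
    logfc_mean, logfc_sd:
        Log2 fold change of a signature gene in its own subtype, drawn
        N(logfc_mean, logfc_sd). The default sd scales with the mean
        (0.375 * |logfc_mean|): effect sizes are heterogeneous across genes,
        and the whole signal vanishes together at logfc_mean = 0.
    cross_logfc_ratio:
        Signature genes also vary across the other subtypes with offsets drawn
        N(0, cross_logfc_ratio * logfc_mean). This keeps signature genes the
        most variable genes panel-wide (subtype markers are graded across
        subtypes, not binary on/off) while the own-subtype offset remains the
        maximum. At logfc_mean = 0 all structure vanishes.
    nb_dispersion:
        Negative-binomial dispersion alpha, variance = mu + alpha * mu**2.
    library_size_logmean, library_size_logsd:
        Natural-log parameters of the per-sample log-normal library size.
    baseline_log2_mean, baseline_log2_sd:
        Per-gene baseline log2 expression, N(mean, sd).
    sig_baseline_log2_mean, sig_baseline_log2_sd:
        Baseline log2 expression of signature genes, drawn from the lower end
        of the expression range: subtype markers are lineage-restricted, low
        outside their own lineage, which is what gives them discriminative
        multiplicative contrast when upregulated.
    batch_location_sd, batch_scale_sd:
        Per-gene batch effects (natural-log location shift sd and log-scale
        factor sd), applied relative to the first batch of each panel.
    purity_low, purity_high:
        Uniform bounds of tumor purity; expected tumor expression is
        purity * subtype profile + (1 - purity) * stromal baseline.
    annotation_fraction:
        Fraction of cell lines whose true subtype is exposed as a prior
        literature annotation in the metadata (the rest are "unknown").
    rng_seed:
        Master seed; every random draw derives its own stream from it.
    """

    n_genes: int = 2000
    k_subtypes: int = 5
    n_cell_lines: int = 56
    n_tumors_per_subtype: tuple[int, ...] = (64, 16, 8, 5)
    subtype_names: tuple[str, ...] = EOC_SUBTYPES
    tumor_subtypes: tuple[str, ...] = TUMOR_SUBTYPES
    n_sig_genes_per_subtype: int = 60
    logfc_mean: float = 2.0
    logfc_sd: float | None = None  # default 0.375 * |logfc_mean|
    cross_logfc_ratio: float = 0.375
    nb_dispersion: float = 0.1
    library_size_logmean: float = 13.1
    library_size_logsd: float = 0.25
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    sig_baseline_log2_mean: float = 3.0
    sig_baseline_log2_sd: float = 1.0
    n_batches_cell_lines: int = 3
    n_batches_tumors: int = 3
    batch_location_sd: float = 0.2
    batch_scale_sd: float = 0.05
    purity_low: float = 0.5
    purity_high: float = 0.9
    annotation_fraction: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.logfc_sd is None:
            self.logfc_sd = 0.375 * abs(self.logfc_mean)
        self.subtype_names = tuple(self.subtype_names)
        self.tumor_subtypes = tuple(self.tumor_subtypes)
        self.n_tumors_per_subtype = tuple(self.n_tumors_per_subtype)
        if len(self.subtype_names) != self.k_subtypes:
            # non-default k: synthesize generic names, all with tumors
            self.subtype_names = tuple(f"S{i + 1}" for i in range(self.k_subtypes))
            self.tumor_subtypes = self.subtype_names
            if len(self.n_tumors_per_subtype) != len(self.tumor_subtypes):
                self.n_tumors_per_subtype = (10,) * len(self.tumor_subtypes)
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_genes",
            "k_subtypes",
            "n_cell_lines",
            "n_sig_genes_per_subtype",
            "n_batches_cell_lines",
            "n_batches_tumors",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")
        if any(n <= 0 for n in self.n_tumors_per_subtype):
            raise ValueError("all tumor counts must be positive")
        if len(self.n_tumors_per_subtype) != len(self.tumor_subtypes):
            raise ValueError("n_tumors_per_subtype must match tumor_subtypes")
        if not set(self.tumor_subtypes) <= set(self.subtype_names):
            raise ValueError("tumor_subtypes must be a subset of subtype_names")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (0.0 < self.purity_low <= self.purity_high <= 1.0):
            raise ValueError(
                f"purity bounds must satisfy 0 < low <= high <= 1, got "
                f"({self.purity_low}, {self.purity_high})"
            )
        if self.k_subtypes * self.n_sig_genes_per_subtype > self.n_genes:
            raise ValueError(
                "k_subtypes * n_sig_genes_per_subtype exceeds n_genes: "
                f"{self.k_subtypes} * {self.n_sig_genes_per_subtype} > {self.n_genes}"
            )
        if not (0.0 <= self.annotation_fraction <= 1.0):
            raise ValueError("annotation_fraction must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RecommendationRules:
    """Thresholds of the cell-line recommendation rule engine.

    Rules (applied with this precedence, each line gets one primary flag):

    i.   avoid — overall median correlation below the ``q_low`` quantile of
         all lines' overall medians.
    ii.  avoid — assigned subtype S but not within the ``top_n`` lines ranked
         by median correlation to S tumors.
    iii. ambiguous — within the ``top_k`` for at least ``multi_subtypes``
         tumor subtypes.
    iv.  potential flag for the tumor-less subtype — assigned to a subtype
         with no tumors and not caught by (iii).
    Otherwise the line is recommended for its assigned subtype.
    """

    q_low: float = 0.25
    top_n: int = 20
    top_k: int = 10
    multi_subtypes: int = 3

    def validate(self) -> None:
        if not (0.0 < self.q_low < 1.0):
            raise ValueError("q_low must be in (0, 1)")
        if self.top_n < 1 or self.top_k < 1 or self.multi_subtypes < 2:
            raise ValueError("invalid recommendation thresholds")
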