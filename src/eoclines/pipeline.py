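"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` executes the stages — simulate (optional), preprocess,
rank-survey (optional), NMF consensus, subtype mapping, correlation, ranking,
recommendation — each writing its outputs under the run directory, and
records a manifest of every emitted file (SHA-256, parameters, timestamps,
package version). A run is reproducible bit-for-bit from its config plus the
master seed for all deterministic stages; stochastic stages (simulation, NMF
restarts) derive their seeds from the master seed and record them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RecommendationRules, SimulationConfig
from .consensus import rank_survey, run_consensus, select_rank
from .io import read_counts, read_metadata, write_expression
from .nmf import derive_seed
from .preprocessing import combat_adjust, mad_filter, size_factors, upper_quartile_normalize, vst_transform
from .ranking import rank_by_correlation, recommend_lines, spearman_matrix
from .simulate import simulate_panel, write_fixture
from .subtyping import map_clusters_to_subtypes

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "rank_survey",
    "nmf",
    "subtype_map",
    "correlate",
    "rank",
    "recommend",
)


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run (YAML-serializable)."""

    out_dir: str = "run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    counts_path: str | None = None  # used when the simulate stage is off
    metadata_path: str | None = None
    tumor_counts_path: str | None = None
    mad_threshold: float = 1.5
    mad_constant: float = 1.4826
    mad_top_n: int | None = 300
    combat_nmf_branch: bool = False
    ranks: tuple[int, ...] = tuple(range(2, 9))
    survey_runs: int = 15
    consensus_rank: int | None = None  # None: take the survey's selection
    consensus_runs: int = 200
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    rules: RecommendationRules = field(default_factory=RecommendationRules)

    def __post_init__(self) -> None:
        full = {s: True for s in STAGES}
        full.update(self.stages or {})
        unknown = set(full) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = full
        self.ranks = tuple(self.ranks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "rules" in raw and raw["rules"] is not None:
            raw["rules"] = RecommendationRules(**raw["rules"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    """Accumulates per-stage provenance and writes ``manifest.json``."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.record: dict = {"version": __version__, "stages": {}}

    def add(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.record["stages"][stage] = {
            "params": params,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {
                str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs
            },
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.record, indent=2, default=str) + "\n")
        return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest record."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out)
    config.to_yaml(out / "config.yaml")
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, False):
            manifest.record["stages"][stage] = {"skipped": True}
            logger.info("stage %s skipped", stage)
            continue
        runner = globals()[f"_stage_{stage}"]
        try:
            runner(config, out, state, manifest)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    manifest.write()
    return manifest.record


def _stage_simulate(config, out, state, manifest):
    sim = config.simulation
    if sim is None:
        raise ValueError("simulate stage enabled but no simulation config given")
    sim = dataclasses.replace(sim, rng_seed=derive_seed(config.seed, 1))
    lines, tumors = simulate_panel(sim)
    files = write_fixture(lines, out / "lines")
    tfiles = write_fixture(tumors, out / "tumors")
    state["lines_counts"] = lines.counts
    state["lines_meta"] = lines.metadata
    state["tumor_counts"] = tumors.counts
    state["tumor_meta"] = tumors.metadata
    manifest.add(
        "simulate",
        {"config": dataclasses.asdict(sim), "derived_seed": sim.rng_seed},
        list(files.values()) + list(tfiles.values()),
    )


def _load_inputs(config, state):
    if "lines_counts" not in state:
        if not config.counts_path or not config.metadata_path:
            raise ValueError(
                "simulate stage disabled: counts_path and metadata_path required"
            )
        counts = read_counts(config.counts_path)
        meta = read_metadata(config.metadata_path)
        line_ids = meta.loc[meta.get("kind", "cell_line") == "cell_line", "sample_id"]
        state["lines_counts"] = counts[list(line_ids)]
        state["lines_meta"] = meta[meta["sample_id"].isin(line_ids)]
        if config.tumor_counts_path:
            tcounts = read_counts(config.tumor_counts_path)
            tids = meta.loc[meta["kind"] == "tumor", "sample_id"]
            state["tumor_counts"] = tcounts[[c for c in tcounts.columns if c in set(tids)]]
            state["tumor_meta"] = meta[meta["sample_id"].isin(state["tumor_counts"].columns)]


def _stage_preprocess(config, out, state, manifest):
    _load_inputs(config, state)
    counts = state["lines_counts"]
    vst = vst_transform(counts, size_factors(counts))
    if config.combat_nmf_branch:
        batches = state["lines_meta"].set_index("sample_id")["batch"]
        vst = combat_adjust(vst, batches)
    filt = mad_filter(
        vst,
        threshold=config.mad_threshold,
        scale_constant=config.mad_constant,
        top_n=config.mad_top_n,
    )
    expr = vst.loc[filt.kept_gene_ids]
    state["vst_filtered"] = expr
    state["mad_genes"] = filt.kept_gene_ids
    outputs = [
        write_expression(
            expr,
            out / "vst_filtered.tsv",
            {
                "mad_threshold": filt.threshold,
                "mad_constant": filt.scale_constant,
                "mad_top_n": filt.top_n,
                "n_genes_kept": len(filt.kept_gene_ids),
            },
        )
    ]
    kept_path = out / "mad_kept.txt"
    kept_path.write_text("\n".join(filt.kept_gene_ids) + "\n")
    outputs.append(kept_path)
    outputs.append(outputs[0].with_suffix(".tsv.json"))

    if "tumor_counts" in state:
        joint = pd.concat([state["lines_counts"], state["tumor_counts"]], axis=1)
        meta = pd.concat([state["lines_meta"], state["tumor_meta"]])
        uq = upper_quartile_normalize(joint, log2=True)
        batches = meta.set_index("sample_id")["batch"].reindex(uq.columns)
        corrected = combat_adjust(uq, batches)
        state["joint_corrected"] = corrected
        outputs.append(
            write_expression(corrected, out / "joint_normalized.tsv", {})
        )
    manifest.add(
        "preprocess",
        {
            "mad_threshold": config.mad_threshold,
            "mad_constant": config.mad_constant,
            "mad_top_n": config.mad_top_n,
            "combat_nmf_branch": config.combat_nmf_branch,
        },
        outputs,
    )


def _stage_rank_survey(config, out, state, manifest):
    V = state["vst_filtered"].to_numpy()
    survey = rank_survey(
        V,
        config.ranks,
        n_runs=config.survey_runs,
        seed=derive_seed(config.seed, 2),
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
    )
    selection = select_rank(survey)
    state["selected_rank"] = selection.rank
    path = out / "survey.tsv"
    survey.table.to_csv(path, sep="\t", index=False)
    sel_path = out / "selected_rank.json"
    sel_path.write_text(
        json.dumps(dataclasses.asdict(selection), indent=2, default=str) + "\n"
    )
    manifest.add(
        "rank_survey",
        {"ranks": list(config.ranks), "n_runs": config.survey_runs,
         "seed": derive_seed(config.seed, 2), "selected": selection.rank},
        [path, sel_path],
    )


def _stage_nmf(config, out, state, manifest):
    V = state["vst_filtered"].to_numpy()
    rank = config.consensus_rank or state.get("selected_rank")
    if rank is None:
        raise ValueError("no factorization rank: set consensus_rank or run the survey")
    result = run_consensus(
        V,
        rank,
        n_runs=config.consensus_runs,
        seed=derive_seed(config.seed, 3),
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
    )
    samples = list(state["vst_filtered"].columns)
    state["consensus"] = result
    state["sample_ids"] = samples
    outputs = []
    consensus_df = pd.DataFrame(result.consensus, index=samples, columns=samples)
    outputs.append(out / "consensus.tsv")
    consensus_df.rename_axis("sample_id").to_csv(outputs[-1], sep="\t")
    labels_df = pd.DataFrame(
        {
            "sample_id": samples,
            "cluster": result.labels,
            "hclust_cluster": result.hclust_labels,
            "silhouette": result.silhouettes,
        }
    )
    outputs.append(out / "labels.tsv")
    labels_df.to_csv(outputs[-1], sep="\t", index=False)
    metrics = {
        "rank": rank,
        "n_runs": config.consensus_runs,
        "seed": derive_seed(config.seed, 3),
        "cophenetic": result.cophenetic,
        "dispersion": result.dispersion,
        "mean_silhouette": float(np.mean(result.silhouettes)),
        "min_silhouette": float(np.min(result.silhouettes)),
        "rss_best": result.rss_best,
    }
    outputs.append(out / "metrics.json")
    outputs[-1].write_text(json.dumps(metrics, indent=2) + "\n")
    genes = list(state["vst_filtered"].index)
    w_df = pd.DataFrame(
        result.best.W, index=genes, columns=[f"metagene_{i+1}" for i in range(rank)]
    )
    outputs.append(out / "W.tsv")
    w_df.rename_axis("gene_id").to_csv(outputs[-1], sep="\t")
    h_df = pd.DataFrame(
        result.best.H, index=[f"metagene_{i+1}" for i in range(rank)], columns=samples
    )
    outputs.append(out / "H.tsv")
    h_df.rename_axis("metagene").to_csv(outputs[-1], sep="\t")
    manifest.add("nmf", {k: metrics[k] for k in ("rank", "n_runs", "seed")}, outputs)


def _stage_subtype_map(config, out, state, manifest):
    samples = state["sample_ids"]
    labels = pd.Series(state["consensus"].labels, index=samples)
    meta = state["lines_meta"].set_index("sample_id")
    annotations = meta["prior_subtype"].reindex(samples)
    assignment = map_clusters_to_subtypes(labels, annotations)
    state["assignment"] = assignment
    path = out / "assignment.tsv"
    assignment.table.to_csv(path, sep="\t", index=False)
    manifest.add("subtype_map", {"n_annotated": int((annotations != "unknown").sum())}, [path])


def _stage_correlate(config, out, state, manifest):
    if "joint_corrected" not in state:
        raise ValueError("correlate stage requires tumor data in preprocessing")
    joint = state["joint_corrected"]
    line_ids = [c for c in joint.columns if c in set(state["lines_counts"].columns)]
    tumor_ids = [c for c in joint.columns if c in set(state["tumor_counts"].columns)]
    genes = [g for g in state["mad_genes"] if g in joint.index]
    corr = spearman_matrix(joint[line_ids], joint[tumor_ids], genes)
    state["corr"] = corr
    tmeta = state["tumor_meta"].set_index("sample_id")
    state["tumor_subtype_series"] = tmeta["true_subtype"].reindex(corr.columns)
    long = corr.stack().rename("rho").reset_index()
    long.columns = ["cell_line", "tumor", "rho"]
    long["subtype"] = long["tumor"].map(tmeta["true_subtype"])
    path = out / "corr.tsv"
    long.to_csv(path, sep="\t", index=False)
    wide = out / "corr_matrix.tsv"
    corr.rename_axis("cell_line").to_csv(wide, sep="\t")
    manifest.add("correlate", {"n_genes": len(genes)}, [path, wide])


def _stage_rank(config, out, state, manifest):
    corr = state["corr"]
    subtypes = state["tumor_subtype_series"]
    frames = []
    for s in sorted(set(subtypes.dropna())):
        ranking = rank_by_correlation(corr, subtypes, s, "median")
        t = ranking.table.copy()
        t.insert(0, "subtype", s)
        frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    state["ranking"] = table
    path = out / "ranking.tsv"
    table.to_csv(path, sep="\t", index=False)
    manifest.add("rank", {"statistic": "median"}, [path])


def _stage_recommend(config, out, state, manifest):
    table = recommend_lines(
        state["corr"],
        state["assignment"],
        state["tumor_subtype_series"],
        config.rules,
    )
    path = out / "recommendations.tsv"
    table.to_csv(path, sep="\t", index=False)
    manifest.add("recommend", dataclasses.asdict(config.rules), [path])
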