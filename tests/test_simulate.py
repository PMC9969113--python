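"""Generator tests: planted structure, moment recovery, determinism, round-trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from eoclines import (
    SimulationConfig,
    apply_batch_effects,
    generate_signatures,
    graded_fidelities,
    simulate_cell_lines,
    simulate_tumors,
    write_fixture,
)
from eoclines.io import read_counts


def test_signature_sets_are_disjoint_and_cover_configured_sizes():
    cfg = SimulationConfig(n_genes=100, k_subtypes=2, n_sig_genes_per_subtype=10)
    sig = generate_signatures(cfg)
    sets = list(sig.signature_gene_index.values())
    assert [len(s) for s in sets] == [10, 10]
    assert len(sets[0] & sets[1]) == 0
    # the other 80 genes sit exactly on the baseline in every subtype
    baseline_rel = sig.baseline_relative
    non_sig = [
        i for i, g in enumerate(sig.genes) if g not in sets[0] | sets[1]
    ]
    assert len(non_sig) == 80
    for ci in range(2):
        np.testing.assert_allclose(
            sig.signatures[non_sig, ci], baseline_rel[non_sig]
        )


def test_degenerate_logfc_distribution_gives_exact_fold_change():
    cfg = SimulationConfig(
        n_genes=100, k_subtypes=2, n_sig_genes_per_subtype=10,
        logfc_mean=2.0, logfc_sd=0.0,
    )
    sig = generate_signatures(cfg)
    for ci, subtype in enumerate(sig.subtypes):
        rows = [sig.genes.index(g) for g in sig.signature_gene_index[subtype]]
        ratio = np.log2(sig.signatures[rows, ci] / sig.baseline_relative[rows])
        np.testing.assert_allclose(ratio, 2.0, atol=1e-12)


def test_signature_generation_is_deterministic_under_fixed_seed():
    cfg = SimulationConfig(rng_seed=42)
    a, b = generate_signatures(cfg), generate_signatures(cfg)
    assert a.signature_gene_index == b.signature_gene_index
    np.testing.assert_array_equal(a.signatures, b.signatures)


def test_signature_config_rejects_oversubscribed_genes():
    with pytest.raises(ValueError, match="exceeds n_genes"):
        SimulationConfig(n_genes=50, k_subtypes=5, n_sig_genes_per_subtype=20)


def test_cell_line_counts_poisson_limit_mean_variance_ratio():
    # dispersion -> 0: per-gene variance/mean ratio approaches 1
    cfg = SimulationConfig(
        n_genes=2000, k_subtypes=2, n_cell_lines=40, n_sig_genes_per_subtype=5,
        nb_dispersion=0.0, library_size_logsd=0.0, batch_location_sd=0.0,
        batch_scale_sd=0.0, logfc_mean=0.0, logfc_sd=0.0, rng_seed=3,
    )
    lines = simulate_cell_lines(generate_signatures(cfg), cfg)
    counts = lines.counts.to_numpy(dtype=float)
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    informative = mean > 20
    assert informative.sum() >= 1000
    ratio = np.median(var[informative] / mean[informative])
    assert abs(ratio - 1.0) < 0.1


def test_signature_gene_fold_change_recovered_in_counts():
    cfg = SimulationConfig(
        n_genes=1000, k_subtypes=2, n_cell_lines=40,
        n_sig_genes_per_subtype=50, logfc_mean=2.0, logfc_sd=0.0,
        cross_logfc_ratio=0.0, library_size_logsd=0.0, rng_seed=9,
    )
    sig = generate_signatures(cfg)
    lines = simulate_cell_lines(sig, cfg)
    meta = lines.metadata
    subtype = sig.subtypes[0]
    in_sub = meta.loc[meta["true_subtype"] == subtype, "sample_id"]
    out_sub = meta.loc[meta["true_subtype"] != subtype, "sample_id"]
    rows = sorted(sig.signature_gene_index[subtype])
    ratio = (
        lines.counts.loc[rows, in_sub].mean(axis=1)
        / lines.counts.loc[rows, out_sub].mean(axis=1)
    )
    # mean count ratio ~ 2**logfc_mean (up to normalization slack)
    assert abs(np.log2(ratio.mean()) - 2.0) < 0.35


def test_same_seed_reproduces_identical_counts():
    cfg = SimulationConfig(n_genes=200, k_subtypes=2, n_cell_lines=8,
                           n_sig_genes_per_subtype=10, rng_seed=7)
    sig = generate_signatures(cfg)
    a = simulate_cell_lines(sig, cfg)
    b = simulate_cell_lines(sig, cfg)
    pd.testing.assert_frame_equal(a.counts, b.counts)


def test_tumors_at_full_purity_match_cell_line_expected_means():
    cfg = SimulationConfig(
        n_genes=300, k_subtypes=2, n_cell_lines=4,
        n_tumors_per_subtype=(2, 2), n_sig_genes_per_subtype=10,
        purity_low=1.0, purity_high=1.0, library_size_logsd=0.0, rng_seed=1,
    )
    sig = generate_signatures(cfg)
    lines = simulate_cell_lines(sig, cfg)
    tumors = simulate_tumors(sig, cfg)
    # purity 1 collapses the mixture: expected means equal per subtype
    for subtype in sig.subtypes:
        lcol = lines.metadata.index[lines.metadata["true_subtype"] == subtype][0]
        tcol = tumors.metadata.index[tumors.metadata["true_subtype"] == subtype][0]
        np.testing.assert_allclose(
            lines.means[:, lcol], tumors.means[:, tcol], rtol=1e-10
        )


def test_half_purity_means_are_convex_combination():
    cfg = SimulationConfig(
        n_genes=300, k_subtypes=2, n_cell_lines=4, n_tumors_per_subtype=(2, 2),
        n_sig_genes_per_subtype=10, purity_low=0.5, purity_high=0.5,
        library_size_logsd=0.0, rng_seed=1,
    )
    sig = generate_signatures(cfg)
    tumors = simulate_tumors(sig, cfg)
    library = np.exp(cfg.library_size_logmean)
    ci = 0
    mix = 0.5 * sig.signatures[:, ci] + 0.5 * sig.baseline_relative
    expected = mix / mix.sum() * library
    tcol = tumors.metadata.index[
        tumors.metadata["true_subtype"] == sig.subtypes[ci]
    ][0]
    np.testing.assert_allclose(tumors.means[:, tcol], expected, rtol=1e-10)


def test_purity_monotonically_degrades_tumor_line_correlation():
    from scipy.stats import spearmanr

    cfg = SimulationConfig(
        n_genes=600, k_subtypes=2, n_cell_lines=2, n_tumors_per_subtype=(30, 1),
        n_sig_genes_per_subtype=60, library_size_logsd=0.0, rng_seed=21,
    )
    sig = generate_signatures(cfg)
    line = simulate_cell_lines(sig, cfg)
    line_col = line.counts.iloc[:, 0]  # subtype 0, fidelity 1
    rhos = []
    for purity in (0.9, 0.6, 0.3):
        pcfg = dataclasses.replace(cfg, purity_low=purity, purity_high=purity)
        tumors = simulate_tumors(sig, pcfg)
        cols = tumors.metadata["true_subtype"] == sig.subtypes[0]
        sub = tumors.counts.loc[:, cols.to_numpy()]
        rhos.append(
            np.mean([spearmanr(line_col, sub[t]).statistic for t in sub.columns])
        )
    assert rhos[0] > rhos[1] > rhos[2]


def test_batch_effects_zero_magnitude_is_identity():
    cfg = SimulationConfig(
        n_genes=200, k_subtypes=2, n_cell_lines=9, n_sig_genes_per_subtype=10,
        batch_location_sd=0.0, batch_scale_sd=0.0, rng_seed=13,
    )
    lines = simulate_cell_lines(generate_signatures(cfg), cfg)
    shifted = apply_batch_effects(lines, cfg)
    pd.testing.assert_frame_equal(lines.counts, shifted.counts)


def test_single_batch_introduces_no_relative_shift():
    cfg = SimulationConfig(
        n_genes=200, k_subtypes=2, n_cell_lines=9, n_sig_genes_per_subtype=10,
        n_batches_cell_lines=1, batch_location_sd=0.8, rng_seed=13,
    )
    lines = simulate_cell_lines(generate_signatures(cfg), cfg)
    shifted = apply_batch_effects(lines, cfg)
    pd.testing.assert_frame_equal(lines.counts, shifted.counts)


def test_batch_location_sd_recovered_from_mean_log_difference():
    cfg = SimulationConfig(
        n_genes=3000, k_subtypes=2, n_cell_lines=20, n_sig_genes_per_subtype=5,
        n_batches_cell_lines=2, batch_location_sd=0.5, batch_scale_sd=0.0,
        logfc_mean=0.0, logfc_sd=0.0, library_size_logsd=0.0, rng_seed=17,
    )
    lines = simulate_cell_lines(generate_signatures(cfg), cfg)
    shifted = apply_batch_effects(lines, cfg)
    log_mu = np.log(shifted.means)
    b = shifted.metadata["batch"].to_numpy()
    diff = (
        log_mu[:, b == "CLB1"].mean(axis=1) - log_mu[:, b == "CLB2"].mean(axis=1)
    )
    assert abs(diff.std() - 0.5) < 0.05


def test_batch_effects_require_batch_labels():
    cfg = SimulationConfig(n_genes=100, k_subtypes=2, n_cell_lines=4,
                           n_sig_genes_per_subtype=5, rng_seed=1)
    lines = simulate_cell_lines(generate_signatures(cfg), cfg)
    lines.metadata.loc[0, "batch"] = np.nan
    with pytest.raises(ValueError, match="batch label"):
        apply_batch_effects(lines, cfg)


def test_fixture_round_trips_through_both_formats(tmp_path, small_panel):
    lines, _ = small_panel
    files = write_fixture(lines, tmp_path)
    tsv = read_counts(files["counts_tsv"])
    mtx = read_counts(files["counts_mtx"])
    pd.testing.assert_frame_equal(tsv, lines.counts.astype(np.int64))
    pd.testing.assert_frame_equal(mtx, tsv)


def test_fixture_snapshot_of_toy_matrix(tmp_path):
    cfg = SimulationConfig(n_genes=3, k_subtypes=2, n_cell_lines=2,
                           n_sig_genes_per_subtype=1, rng_seed=0)
    lines = simulate_cell_lines(generate_signatures(cfg), cfg)
    write_fixture(lines, tmp_path)
    header = (tmp_path / "counts.tsv").read_text().splitlines()[0]
    assert header == "gene_id\tCL001\tCL002"
    mtx_lines = (tmp_path / "counts.mtx").read_text().splitlines()
    assert mtx_lines[0].startswith("%%MatrixMarket matrix coordinate integer")


def test_fixture_bytes_are_deterministic(tmp_path, small_config):
    from eoclines import simulate_panel

    lines_a, _ = simulate_panel(small_config)
    lines_b, _ = simulate_panel(small_config)
    fa = write_fixture(lines_a, tmp_path / "a")
    fb = write_fixture(lines_b, tmp_path / "b")
    for key in fa:
        assert fa[key].read_bytes() == fb[key].read_bytes()


def test_graded_fidelities_layout():
    cfg = SimulationConfig(n_genes=200, k_subtypes=5, n_cell_lines=31,
                           n_sig_genes_per_subtype=10, rng_seed=1)
    fid = graded_fidelities(cfg, n_per_subtype=6, poor_line_fidelity=0.05)
    assert fid[0] == 0.05
    # each subtype receives the full grade ladder exactly once
    for subtype_idx in range(5):
        members = [i for i in range(1, 31) if i % 5 == subtype_idx]
        grades = sorted(fid[members], reverse=True)
        np.testing.assert_allclose(grades, np.linspace(1.0, 0.35, 6))


def test_cluster_recovery_monotone_in_effect_size():
    """Downstream ARI is non-decreasing in the planted log fold change."""
    from eoclines import run_consensus, simulate_panel
    from eoclines.preprocessing import mad_filter, vst_transform
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for logfc in (0.5, 1.0, 2.0):
        cfg = SimulationConfig(rng_seed=4, logfc_mean=logfc)
        lines, _ = simulate_panel(cfg)
        vst = vst_transform(lines.counts)
        kept = mad_filter(vst, top_n=300).kept_gene_ids
        res = run_consensus(
            vst.loc[kept].to_numpy(), 5, n_runs=10, seed=4, max_iter=1000
        )
        aris.append(
            adjusted_rand_score(lines.metadata["true_subtype"], res.labels)
        )
    assert aris[0] <= aris[1] + 0.05 and aris[1] <= aris[2] + 0.05
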