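import pytest

from eoclines import SimulationConfig, simulate_panel
from eoclines.preprocessing import mad_filter, vst_transform


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale configuration: 3 subtypes, small panel, fast to simulate."""
    return SimulationConfig(
        n_genes=400,
        k_subtypes=3,
        n_cell_lines=18,
        n_tumors_per_subtype=(6, 6, 6),
        n_sig_genes_per_subtype=25,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def default_fixture():
    """The default cell-line fixture: 56 lines, 5 planted subtypes."""
    config = SimulationConfig(rng_seed=5)
    lines, _ = simulate_panel(config)
    return config, lines


@pytest.fixture(scope="session")
def default_fixture_vst(default_fixture):
    """VST + MAD-filtered expression of the default fixture."""
    config, lines = default_fixture
    vst = vst_transform(lines.counts)
    filt = mad_filter(vst, top_n=300)
    return vst.loc[filt.kept_gene_ids], lines.metadata
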