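"""Shared fixtures: session-scoped synthetic datasets and derived objects."""

from types import SimpleNamespace

import pytest

from genarch import io as gio
from genarch.core import WindowGrid
from genarch.simulate import SimulationConfig, simulate
from genarch.snp import call_inter_individual, classify_pileup
from genarch.tandem_repeats import parse_trf_dat


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The standard study-condition dataset (42 Mb, planted features)."""
    out = tmp_path_factory.mktemp("sim_default")
    config = SimulationConfig.default(11)
    paths, truth = simulate(config, out)
    return SimpleNamespace(config=config, paths=paths, truth=truth, dir=out)


@pytest.fixture(scope="session")
def feature_free_sim(tmp_path_factory):
    """A homogeneous genome with no planted features (negative control)."""
    out = tmp_path_factory.mktemp("sim_ff")
    config = SimulationConfig.feature_free(7)
    paths, truth = simulate(config, out)
    return SimpleNamespace(config=config, paths=paths, truth=truth, dir=out)


@pytest.fixture(scope="session")
def default_genome(default_sim):
    return gio.read_fasta(default_sim.paths["genome_fasta"])


@pytest.fixture(scope="session")
def default_grid(default_genome):
    return WindowGrid.from_genome(default_genome, 100_000)


@pytest.fixture(scope="session")
def default_records(default_sim):
    return parse_trf_dat(default_sim.paths["trf_dat"])


@pytest.fixture(scope="session")
def default_calls(default_sim, default_genome):
    sites = gio.read_pileup_tsv(default_sim.paths["pileup"])
    return classify_pileup(sites, default_genome.gaps)


@pytest.fixture(scope="session")
def default_inter(default_sim, default_calls):
    consensus = gio.read_consensus_tsv(default_sim.paths["consensus"])
    return call_inter_individual(default_calls, consensus)


@pytest.fixture(scope="session")
def default_genes(default_sim):
    return gio.read_genes_gff3(default_sim.paths["genes_gff3"])


@pytest.fixture(scope="session")
def default_events(default_sim):
    from genarch.organelle import filter_hits, merge_hits_to_events

    events = {}
    for organelle in ("cp", "mt"):
        hits = filter_hits(gio.read_hits_tabular(default_sim.paths[f"hits_{organelle}"]))
        events[organelle] = merge_hits_to_events(hits, organelle=organelle)
    return events
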