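import json
from pathlib import Path

import pytest

from mavemap import io as mio, scoring, simulate

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_tables():
    counts = mio.read_count_table(DATA / "toy_counts.tsv")
    wt = mio.read_count_table(DATA / "toy_wt_counts.tsv")
    expected = json.loads((DATA / "toy_expected.json").read_text())
    return counts, wt, expected


@pytest.fixture(scope="session")
def toy_scores(toy_tables):
    counts, wt, _ = toy_tables
    return scoring.score_map(counts, wt, protein_length=100)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size study conditions for fast unit/property tests."""
    return simulate.SimulationConfig(
        protein_length=80, tiles_per_region=2, reads_per_tile=50_000,
        rng_seed=5)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def default_experiment():
    """The generator's default study conditions (full-length protein,
    200k reads per tile), fixed seed."""
    return simulate.simulate_experiment(simulate.SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def default_maps(default_experiment):
    exp = default_experiment
    region_of = dict(zip(exp.variant_table["tile"], exp.variant_table["region"]))
    maps = {}
    logs = {}
    for isoform in exp.config.isoforms:
        counts = exp.counts[exp.counts["isoform"] == isoform].drop(columns="isoform")
        wt = exp.wt_controls[exp.wt_controls["isoform"] == isoform].drop(
            columns="isoform")
        maps[isoform], logs[isoform] = scoring.score_map(
            counts, wt, exp.config.protein_length, region_of, isoform=isoform)
    return maps, logs
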