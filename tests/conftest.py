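import numpy as np
import pytest

from drugcombo.enrichment import profile_all
from drugcombo.features import build_matrix, split_matrix
from drugcombo.interactions import ScoreTable
from drugcombo.synthetic import SignalConfig, SynthConfig, generate


def make_table(kind, entries):
    """ScoreTable from a {(a, b): score} dict."""
    t = ScoreTable(kind)
    for (a, b), s in entries.items():
        t.add(a, b, s)
    return t


def build_labelled_matrix(config: SynthConfig):
    """Run generate -> enrich -> featurize; returns (dataset, X, y, names)."""
    data = generate(config)
    profiles = profile_all(data.drugs.values(), data.ppi, data.annotation)
    df = build_matrix(data.labels, data.drugs, data.chem, data.ppi, profiles)
    X, y, names = split_matrix(df)
    return data, X, y, names


SMALL_SYNTH = SynthConfig(
    n_drugs=30,
    n_proteins=200,
    universe_size=2000,
    n_pathways=20,
    n_positives=20,
    negative_ratio=3,
    seed=11,
    signal=SignalConfig(chem_shift=400, cross_ppi_boost=0.3, n_signal_pathways=4),
)


@pytest.fixture(scope="session")
def small_dataset():
    """One small planted-signal dataset shared across tests (read-only)."""
    return generate(SMALL_SYNTH)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    data = small_dataset
    profiles = profile_all(data.drugs.values(), data.ppi, data.annotation)
    df = build_matrix(data.labels, data.drugs, data.chem, data.ppi, profiles)
    X, y, names = split_matrix(df)
    return data, X, y, names
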