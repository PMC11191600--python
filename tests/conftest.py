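"""Shared fixtures.

The expensive objects — the default-scale synthetic campaign (2000 training
molecules, 20,000-molecule deck, seed 17) and its four trained receptor
models — are built once per session and shared by the campaign-level tests.
Smaller fixtures cover unit-scale needs.
"""

from __future__ import annotations

import warnings

import pytest

from d4screen.evaluation import evaluate_selection
from d4screen.features import FingerprintConfig, featurize_library
from d4screen.labels import RECEPTORS, label_matrix, label_table
from d4screen.qsar import train_receptor_model
from d4screen.screen import FunnelConfig, screen_library, select_candidates
from d4screen.synthdata import BenchmarkConfig, FragmentGrammar, make_benchmark


@pytest.fixture(scope="session")
def tiny_grammar() -> FragmentGrammar:
    """2 cores x 3 north x 3 south = 18 enumerable products."""
    return FragmentGrammar(
        cores=("C1CN([*:1])CCN1[*:2]", "[*:1]N1CCC(CC1)[*:2]"),
        north_caps=("[*:1]C(=O)c1ccccc1", "[*:1]C(=O)c1ccncc1", "[*:1]C(=O)C1CC1"),
        south_caps=("[*:2]Cc1ccccc1", "[*:2]Cc1ccc(F)cc1", "[*:2]CCc1ccccc1"),
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast, fully functional campaign for unit-level tests."""
    return make_benchmark(
        BenchmarkConfig(n_train=300, n_screen=1500, train_pool=900, seed=5)
    )


@pytest.fixture(scope="session")
def default_benchmark():
    """The study-condition campaign: n_train=2000, n_screen=20,000, seed 17."""
    return make_benchmark(BenchmarkConfig())


@pytest.fixture(scope="session")
def trained_models(default_benchmark):
    """Four receptor models trained on the default campaign (seed 17)."""
    bench = default_benchmark
    config = FingerprintConfig()
    X, ids = featurize_library(bench.train_records, config)
    labels = label_table(bench.measurements)
    models = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for receptor in RECEPTORS:
            Y = label_matrix(labels, receptor, ids)
            models[receptor] = train_receptor_model(
                X, Y, receptor, feature_config=config, seed=17
            )
    return {"models": models, "X": X, "ids": ids, "labels": labels}


@pytest.fixture(scope="session")
def campaign(default_benchmark, trained_models):
    """Full funnel run on the default deck: scores, selection, report."""
    funnel = FunnelConfig()
    scores = screen_library(trained_models["models"], default_benchmark.deck_records, funnel)
    selected = select_candidates(scores, funnel)
    report = evaluate_selection(selected, default_benchmark.truth, scores)
    return {"scores": scores, "selected": selected, "report": report, "funnel": funnel}
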