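"""Shared fixtures: generated duplexes, probe complexes and a toy ensemble."""

from __future__ import annotations

import pytest
from hypothesis import settings

import helixspec as hx
from helixspec.model import ModelConfig
from helixspec.train import datapoints_from_corpus, train_cross_validation

settings.register_profile("suite", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("suite")

SEQ12 = "ACGTACGTACGT"


@pytest.fixture(scope="session")
def bdna12() -> list:
    return hx.make_bdna(SEQ12, seed=1)


@pytest.fixture(scope="session")
def pairs12(bdna12):
    return hx.detect_base_pairs(bdna12)


@pytest.fixture(scope="session")
def helix12(pairs12):
    return hx.build_sym_helix(pairs12)


@pytest.fixture(scope="session")
def probe_datapoint():
    """12-bp duplex with a donor probe at pair 5 and an acceptor at pair 7."""
    nts = hx.make_bdna(SEQ12, seed=1)
    return hx.plant_probes(
        nts,
        [(5, hx.ProbeRule("donor", "major")),
         (7, hx.ProbeRule("acceptor", "major"))],
        seed=2,
    )


@pytest.fixture(scope="session")
def toy_corpus():
    return hx.generate_corpus(30, seed=7)


@pytest.fixture(scope="session")
def toy_ensemble(toy_corpus):
    """Small 5-fold ensemble trained on the toy corpus (shared, read-only)."""
    dataset = datapoints_from_corpus(toy_corpus)
    config = ModelConfig(seed=0)
    ensemble, histories = train_cross_validation(
        config, dataset, k=5, seed=3, epochs=10, patience=10
    )
    return ensemble, histories, dataset
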