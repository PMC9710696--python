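"""Shared fixtures: small species models and cheaply trained CNNs.

Everything here is scaled down (few filters, short inputs, few windows) so
the unit suite stays fast; the full-scale study conditions live in
tests/test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from genomicstyle import feature_cnn as fc
from genomicstyle import synthetic
from genomicstyle.seqio import DnaSequence


def tiny_config(n_classes: int = 3, n_filters: int = 4, input_length: int = 256,
                seed: int = 0) -> fc.FeatureCnnConfig:
    """Eight-module config small enough for instant forward passes."""
    return fc.FeatureCnnConfig.default(
        n_classes=n_classes, seed=seed, n_filters=n_filters, input_length=input_length
    )


@pytest.fixture(scope="session")
def tiny_model() -> fc.FeatureCnn:
    """Untrained 4-filter CNN on 256 bp inputs."""
    return fc.build_model(tiny_config())


@pytest.fixture(scope="session")
def species_pair() -> list[synthetic.SpeciesModel]:
    """Two synthetic species with a large (0.3 vs 0.7) GC gap."""
    return [
        synthetic.sample_species_model(seed=11, gc_target=0.3, divergence=0.05,
                                       species_id="low_gc"),
        synthetic.sample_species_model(seed=12, gc_target=0.7, divergence=0.05,
                                       species_id="high_gc"),
    ]


@pytest.fixture(scope="session")
def gc2_training_set(species_pair) -> synthetic.LabeledDataset:
    return synthetic.make_pretraining_set(species_pair, windows_per_species=200, seed=21)


@pytest.fixture(scope="session")
def gc2_model(gc2_training_set) -> fc.FeatureCnn:
    """An 8-filter CNN trained for 5 epochs on the two-species GC task."""
    model = fc.build_model(fc.FeatureCnnConfig.default(n_classes=2, seed=3, n_filters=8))
    model, _ = fc.train(model, gc2_training_set, epochs=5, batch_size=32, seed=5)
    return model


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    letters = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(letters), size=length, p=probs))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_seq(residues: str, id: str = "seq") -> DnaSequence:
    return DnaSequence(id=id, residues=residues)
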