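import numpy as np
import pytest

from virokind.cnn import ClassifierConfig, build_model
from virokind.experiments import separability_experiment
from virokind.sgt import SequenceRecord, encode_batch, stack_weights
from virokind.simulate import fragment_genomes, perturbed_source_pair, sample_genome


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Small-but-real config: cheap to train, same layer stack."""
    return ClassifierConfig(n_filters=6, dense_units=8, epochs=6, seed=3,
                            dropout_p=0.1)


@pytest.fixture(scope="session")
def tiny_trained():
    """A small classifier trained on an easy synthetic group-D task.

    Used by pipeline tests that need a real weights file; accuracy is
    incidental, mechanics are not.
    """
    rng = np.random.default_rng(5)
    pos, neg = perturbed_source_pair(divergence=0.5, seed=5)
    records, labels = [], []
    for src in (pos, neg):
        for g in range(8):
            genome = sample_genome(src, 4000, rng)
            gen = SequenceRecord(f"{src.label}_g{g}", genome.bases)
            frags = fragment_genomes([(gen, src.label)], "D", 6, rng)
            records.extend(frags.records)
            labels.extend(frags.labels)
    cfg = ClassifierConfig(n_filters=6, dense_units=8, epochs=8, seed=5,
                           dropout_p=0.1)
    x = stack_weights(encode_batch(records, kappa=cfg.kappa))
    y = np.zeros((len(labels), 2), dtype=np.float32)
    for i, lbl in enumerate(labels):
        y[i, 0 if lbl == pos.label else 1] = 1.0
    model = build_model(cfg)
    model.fit(x, y)
    return model


@pytest.fixture(scope="session")
def separability():
    """The full-scale synthetic experiment (default architecture).

    Session-scoped: trains once (~minutes) and is shared by the
    length-trend and error-robustness checks.
    """
    return separability_experiment(seed=7)
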