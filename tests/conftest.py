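import numpy as np
import pytest

from evcoder import (AutoencoderConfig, GeneratorSpec, gen_profiles,
                     train_autoencoder)
from evcoder.stats import ev_table


@pytest.fixture
def toy_fasta(tmp_path):
    """Aligned FASTA: 3 records, 5 columns."""
    path = tmp_path / "toy.fasta"
    path.write_text(">s1\nAAAGC\n>s2\nAAAG-\n>s3\nGAAX-\n")
    return path


@pytest.fixture(scope="session")
def small_corpus():
    """2,000 sorted synthetic profiles plus their EV statistics."""
    profiles = gen_profiles(GeneratorSpec(n_columns=2000, seed=7), sort=True)
    X = np.stack([p.p for p in profiles])
    return profiles, X, ev_table(profiles)


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A quickly trained 2-unit model for inference-contract tests."""
    _, X, _ = small_corpus
    cfg = AutoencoderConfig(seed=11, pretrain_epochs=3, finetune_epochs=5)
    return train_autoencoder(X, cfg)
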