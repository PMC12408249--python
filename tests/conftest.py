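import numpy as np
import pytest

from bsinet.io_cli import (assemble_pairs, featurize_corpus, load_corpus,
                           model_config_for)
from bsinet.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_corpus_dir(tmp_path_factory):
    """Default planted corpus (seed 1) written to disk once per session."""
    out = tmp_path_factory.mktemp("corpus_default")
    return generate(SyntheticConfig(seed=1)).write(out)


@pytest.fixture(scope="session")
def default_corpus(default_corpus_dir):
    return load_corpus(default_corpus_dir)


@pytest.fixture(scope="session")
def default_features(default_corpus):
    return featurize_corpus(default_corpus, d_emb=1024)


@pytest.fixture(scope="session")
def default_pairs(default_corpus, default_features):
    return assemble_pairs(default_corpus, default_features)


@pytest.fixture(scope="session")
def default_model_cfg(default_corpus, default_features):
    return model_config_for(default_corpus, default_features)


TINY = SyntheticConfig(n_small=30, n_biotech=10, n_targets=12, n_classes=4,
                       n_sm_clusters=3, n_bt_clusters=2, seed=7)

TINY_NET = dict(gat1_out=8, gat1_heads=2, gat2_out=8, gat2_heads=2,
                fc_out=16, mlp_hidden=(32, 16), max_epochs=2, batch_size=64)


@pytest.fixture(scope="session")
def tiny_corpus_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus_tiny")
    return generate(TINY).write(out)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_corpus_dir):
    return load_corpus(tiny_corpus_dir)


@pytest.fixture(scope="session")
def tiny_features(tiny_corpus):
    return featurize_corpus(tiny_corpus, d_emb=64)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_corpus, tiny_features):
    return assemble_pairs(tiny_corpus, tiny_features)


@pytest.fixture(scope="session")
def tiny_model_cfg(tiny_corpus, tiny_features):
    return model_config_for(tiny_corpus, tiny_features, **TINY_NET)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
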