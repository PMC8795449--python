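"""Shared fixtures.

The expensive fixture is a VAE trained on the standard synthetic study
family (width 64, 2000 sequences, one designed coupled pair, identity
gradient 40-100%, 2% gaps) for 20 epochs. It is session-scoped: sampling
behavior, fidelity statistics, and latent-geometry tests all interrogate the
same trained model.
"""

import numpy as np
import pytest

from famvae import (
    FamilyConfig,
    ModelConfig,
    SplitConfig,
    TrainConfig,
    build_model,
    encode_alignment,
    generate_family,
    split_train_test,
    train,
)

# study conditions for the end-to-end checks
FAMILY = dict(L=64, N=2000, seed=11, n_coupled=1, gap_rate=0.02)
TOY_MODEL = dict(latent_dim=16, encoder_filters=(32, 24, 16),
                 decoder_filters=(16, 24, 32), batch_norm=True)
TOY_TRAIN = dict(epochs=20, batch_size=128, learning_rate=3e-3, seed=3)


@pytest.fixture(scope="session")
def toy_family():
    cfg = FamilyConfig.random(**FAMILY)
    aln = generate_family(cfg)
    return cfg, aln


@pytest.fixture(scope="session")
def trained_toy(toy_family):
    """Unweighted VAE trained on the synthetic family (distribution fidelity).

    Batches are drawn uniformly with replacement so model samples are
    comparable to the raw training alignment statistics.
    """
    cfg, aln = toy_family
    data = encode_alignment(aln)
    model = build_model(ModelConfig(L=cfg.L, **TOY_MODEL), seed=1)
    train_ids, test_ids = split_train_test(aln, SplitConfig(seed=2))
    index = {sid: i for i, sid in enumerate(aln.ids)}
    tri = [index[s] for s in train_ids]
    tei = [index[s] for s in test_ids]
    model, history = train(
        model, data, tri, tei, np.ones(len(tri)), TrainConfig(**TOY_TRAIN)
    )
    return cfg, aln, model, history
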