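import numpy as np
import pytest

import perturbflow as pf

SEED = 1


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset with known loadings, axis and labels."""
    cfg = pf.SyntheticConfig(
        n_cells=400, n_genes=60, latent_dim=4, seed=SEED, n_effect_genes=6
    )
    cm, labels, gt = pf.generate(cfg)
    return cfg, cm, labels, gt


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained NB β-VAE with binary and continuous aux heads."""
    cfg, cm, labels, gt = tiny_dataset
    heads = [
        pf.AuxHeadSpec("condition", "binary", loss_weight=10.0, label_fraction=0.1),
        pf.AuxHeadSpec("time", "continuous", loss_weight=1.0, label_fraction=0.1),
    ]
    mc = pf.ModelConfig(
        latent_dim=4,
        encoder_hidden=(64, 32),
        max_epochs=60,
        batch_size=64,
        patience=15,
        learning_rate=3e-3,
        seed=SEED,
        aux_heads=heads,
    )
    split = pf.split_data(cm, seed=SEED)
    model, hist = pf.train(
        mc, cm, split, {"condition": labels["condition"], "time": labels["time"]}
    )
    return model, hist, split


@pytest.fixture(scope="session")
def knockdown_run():
    """Full-scale knockdown simulation plus trained model and embeddings."""
    cfg = pf.preset_config("knockdown", seed=SEED)
    cm, labels, gt = pf.generate(cfg)
    mc = pf.ModelConfig(
        latent_dim=8,
        encoder_hidden=(128, 64),
        max_epochs=30,
        batch_size=256,
        patience=10,
        seed=SEED,
    )
    split = pf.split_data(cm, seed=SEED)
    model, hist = pf.train(mc, cm, split)
    nm = pf.normalize_log1p(cm)
    emb, _ = model.encode(nm.values)
    return dict(
        cfg=cfg, cm=cm, labels=labels, gt=gt, model=model, emb=emb, history=hist
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
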