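"""Shared fixtures: small synthetic cohorts and a pretrained miniature base model.

The session-scoped ``tiny_base`` fixture pretrains a miniature 3-block network
on a 16³ cohort once and reuses it in the transfer-learning, meta-matching and
interpretation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from metamatch.benchmark import pretrain_base_model
from metamatch.sfcn import SFCNConfig, TrainConfig
from metamatch.synthetic import SyntheticConfig, make_meta_benchmark


TINY_GRID = (16, 16, 16)


def tiny_synth_config(**overrides) -> SyntheticConfig:
    defaults = dict(n=260, grid_shape=TINY_GRID, n_latents=3,
                    blob_radius_range=(2.0, 3.5), phenotype_noise_var=0.1,
                    voxel_noise_std=0.05, seed=42)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_bench():
    """260 participants on a 16³ grid: 3 meta-training phenotypes, 2 meta-test
    phenotypes correlated 0.8 / 0.3 with their nearest training phenotype."""
    return make_meta_benchmark(tiny_synth_config(), n_train_phenos=3,
                               n_test_phenos=2, max_corr_targets=[0.8, 0.3],
                               n_meta_test=80)


@pytest.fixture(scope="session")
def tiny_base(tiny_bench):
    """Miniature pretrained base model (3 blocks, 16³ input, 3 outputs)."""
    cfg = SFCNConfig(input_shape=TINY_GRID, channels=(4, 8, 8),
                     kernel_sizes=(3, 3, 1), dropout_rate=0.2)
    tc = TrainConfig(lr=0.03, max_epochs=16, patience=6, lr_step=8, seed=0)
    return pretrain_base_model(tiny_bench, config=cfg, train_config=tc)


@pytest.fixture(scope="session")
def tiny_pool(tiny_bench, tiny_base):
    """Cached meta-test trunk features, base predictions, ICV and targets."""
    from metamatch.benchmark import _build_pool

    return _build_pool(tiny_bench, tiny_base, ("mm-stack", "transfer"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
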