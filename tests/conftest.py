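"""Shared fixtures.

The expensive fixture is ``trained_pipeline``: one desk-scale training run of
the full cascade (coarse band proposer + three per-edge models) on synthetic
phantoms, shared session-wide by every test that needs converged models.
"""

from __future__ import annotations

import numpy as np
import pytest

from octlayers.phantom import PhantomSpec, generate_bscan
from octlayers.pipeline import PipelineConfig, train_pipeline

# desk-scale phantom geometry: 128 x 256 scans, drusen present
N_TRAIN = 48
N_TEST_AMD = 10
N_TEST_CTRL = 6
SEED = 1234


def small_spec(width: int = 256, height: int = 128, **kw) -> PhantomSpec:
    return PhantomSpec.scaled(width=width, height=height, **kw)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return small_spec(drusen_count_mean=2.5)


@pytest.fixture(scope="session")
def control_spec() -> PhantomSpec:
    return small_spec(drusen_count_mean=0.0)


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    return PipelineConfig.desk_scale(seed=SEED)


@pytest.fixture(scope="session")
def trained_pipeline(phantom_spec, control_spec, desk_config):
    """(models, histories, held-out scans) from one desk-scale training run.

    Held-out scans are a dict scan_id -> (image, ground truth, group) with
    drusen-bearing ("amd-like") and drusen-free ("control-like") phantoms.
    """
    train = [generate_bscan(phantom_spec, SEED + i) for i in range(N_TRAIN)]
    models, hist = train_pipeline(train, desk_config)
    held_out = {}
    for i in range(N_TEST_AMD):
        img, gt = generate_bscan(phantom_spec, SEED + 10_000 + i)
        held_out[f"amd_{i:02d}"] = (img, gt, "amd-like")
    for i in range(N_TEST_CTRL):
        img, gt = generate_bscan(control_spec, SEED + 20_000 + i)
        held_out[f"ctrl_{i:02d}"] = (img, gt, "control-like")
    return models, hist, held_out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
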