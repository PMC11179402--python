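"""Shared fixtures: small deterministic cohorts, probe models, configs."""

import dataclasses

import numpy as np
import pytest

from sfmap.occlusion import OcclusionSpec
from sfmap.pipeline import desk_config
from sfmap.preprocess import ProcessedVolume
from sfmap.regressor import _pool_features
from sfmap.synthetic_cohort import SyntheticCohortConfig, generate_cohort
from sfmap.vf_grid import N_POINTS, default_normative


@pytest.fixture(scope="session")
def norm():
    return default_normative()


@pytest.fixture(scope="session")
def small_cohort_config():
    """Ten-eye cohort at the default desk geometry."""
    return dataclasses.replace(SyntheticCohortConfig(), n_eyes=10, seed=12345)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config, norm):
    return generate_cohort(small_cohort_config, norm)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_volume(rng):
    """An 8x8x8 processed volume (2x2x2 patch grid at patch 4)."""
    return ProcessedVolume(
        intensity=rng.uniform(0.2, 0.8, size=(8, 8, 8)),
        voxel_spacing_um=(60.0, 60.0, 7.8125),
        disc_center_vox=(4.0, 4.0),
        eye_id="tiny", scan_date=0.0,
    )


class LinearProbeModel:
    """pred = features @ W + c on pooled (patch-mean) features."""

    def __init__(self, input_shape, pool=(4, 4, 4), seed=0):
        self.input_shape = tuple(input_shape)
        self.pool = pool
        g = np.random.default_rng(seed)
        n_feat = int(np.prod([s // p for s, p in zip(input_shape, pool)]))
        self.W = g.normal(size=(n_feat, N_POINTS))
        self.c = g.normal(size=N_POINTS)

    def predict(self, volume):
        vol = volume.intensity if hasattr(volume, "intensity") else np.asarray(volume)
        return _pool_features(vol, self.pool) @ self.W + self.c

    def predict_many(self, volumes):
        return np.stack([self.predict(v) for v in np.asarray(volumes)])


class ConstantModel:
    """Always predicts the same 52-vector, whatever the input."""

    def __init__(self, value=20.0):
        self.out = np.full(N_POINTS, float(value))

    def predict(self, volume):
        return self.out.copy()

    def predict_many(self, volumes):
        return np.tile(self.out, (len(volumes), 1))


@pytest.fixture
def linear_probe(tiny_volume):
    return LinearProbeModel(tiny_volume.intensity.shape)


@pytest.fixture
def constant_model():
    return ConstantModel()


@pytest.fixture
def occ_spec():
    return OcclusionSpec()


@pytest.fixture
def fast_pipeline_config(tmp_path):
    """Small, quick full-pipeline configuration writing under tmp_path."""
    cfg = desk_config(seed=7, output_dir=str(tmp_path / "run"), n_eyes=10, epochs=3)
    return cfg
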