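import numpy as np
import pytest

from planarquant.grid import VoxelGrid
from planarquant.phantom import Organ, PhantomSpec, build_phantom
from planarquant.pipeline import PipelineConfig, slab_subject_spec

DEFAULT_SPACING = (2.21, 2.21, 4.42)


@pytest.fixture
def rng():
    return np.random.default_rng(20160607)


@pytest.fixture
def slab_cfg():
    """Small noiseless slab configuration (t_k=4, t_p=20, d_k=5 cm)."""
    return PipelineConfig(
        cohort="slab",
        grid_shape=(64, 128, 32),
        voxel_spacing=DEFAULT_SPACING,
        psf_fwhm_mm=0.0,
        poisson=False,
        body_source="labels",
        n_subjects=1,
    )


@pytest.fixture
def slab_phantom(slab_cfg):
    return build_phantom(slab_subject_spec(slab_cfg, kidney_conc=1000.0))


@pytest.fixture
def body_only_spec():
    return PhantomSpec(
        grid_shape=(32, 32, 16),
        voxel_spacing=DEFAULT_SPACING,
        body=Organ(
            "body_shape", "ellipsoid", (35.0, 35.0, 35.0), (28.0, 28.0, 30.0), 1.0, 0.0
        ),
    )


def make_grid(data, spacing=DEFAULT_SPACING):
    return VoxelGrid(np.asarray(data, dtype=float), spacing)
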