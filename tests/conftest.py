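import numpy as np
import pytest

from lesionconn import SyntheticConfig
from lesionconn.synthetic import build_atlas, build_tumor_mask, render_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cfg():
    """Desk-scale synthetic conditions: 20 parcels on a 6^3 grid, 80 frames."""
    return SyntheticConfig(
        seed=11,
        n_rois=20,
        grid_shape=(6, 6, 6),
        T=80,
        n_patients=4,
        n_controls=4,
        n_lesioned_rois=3,
    )


@pytest.fixture
def small_atlas(small_cfg):
    return build_atlas(small_cfg)


@pytest.fixture
def small_tumor(small_cfg, small_atlas):
    return build_tumor_mask(small_cfg, small_atlas)


@pytest.fixture(scope="session")
def rendered_cohort(tmp_path_factory):
    """A rendered on-disk cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(
        seed=42,
        n_rois=20,
        grid_shape=(6, 6, 6),
        T=60,
        n_patients=4,
        n_controls=4,
        n_lesioned_rois=3,
    )
    out = tmp_path_factory.mktemp("cohort")
    manifest = render_cohort(cfg, out)
    return cfg, out, manifest
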