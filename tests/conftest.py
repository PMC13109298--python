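import numpy as np
import pytest

from canoplot.backends import ClassicalBackend
from canoplot.prompts import build_layout, segment_rows, vegetation_index
from canoplot.synthetic import FieldConfig, generate_field


@pytest.fixture(scope="session")
def small_field():
    """A 3 x 4 trial at 2 cm/px: fast enough for per-module tests."""
    cfg = FieldConfig(n_ranges=3, n_beds=4, gsd_cm=2.0, seed=1)
    ortho, dsm, truth = generate_field(cfg)
    return cfg, ortho, dsm, truth


@pytest.fixture(scope="session")
def segmented_field():
    """A 3 x 4 trial at 1 cm/px with sloped terrain, segmented into row masks."""
    cfg = FieldConfig(
        n_ranges=3, n_beds=4, gsd_cm=1.0, seed=2, terrain_slope=(0.005, -0.003)
    )
    ortho, dsm, truth = generate_field(cfg)
    veg = vegetation_index(ortho.values)
    layout = build_layout(veg, cfg.gsd_cm)
    labels = segment_rows(ClassicalBackend(), ortho.values, layout)
    return cfg, ortho, dsm, truth, veg, layout, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
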