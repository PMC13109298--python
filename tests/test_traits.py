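"""Canopy-height extraction, modality fusion, dataset building, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from canoplot.traits import (
    PlotPatch,
    TrainSpec,
    build_dataset,
    evaluate_trait_classifier,
    extract_canopy_height,
    fuse_ndsm_rgb,
    train_trait_classifier,
)


def _patch(ndsm=None, rgb=None, center_y=112.0, **kw):
    if ndsm is None:
        ndsm = np.zeros((224, 224))
    if rgb is None:
        rgb = np.full((224, 224, 3), 100, np.uint8)
    return PlotPatch(rgb=rgb, ndsm=ndsm, center_y=center_y, **kw)


class TestExtractCanopyHeight:
    def test_mean_of_half_maxima(self):
        nd = np.zeros((224, 224))
        nd[50, 100] = 0.30  # top half
        nd[180, 100] = 0.20  # bottom half
        assert extract_canopy_height(_patch(ndsm=nd)) == pytest.approx(25.0)

    def test_all_zero_is_zero(self):
        assert extract_canopy_height(_patch()) == 0.0

    def test_p95_resists_outlier(self):
        """95th percentile of {0.1 x 99, 1.0 x 1} per half is 0.1, not 1.0."""
        nd = np.zeros((224, 224))
        top = np.full(100, 0.1)
        top[0] = 1.0
        nd[10, :100] = top
        nd[150, :100] = top
        got = extract_canopy_height(_patch(ndsm=nd), stat="p95")
        # halves are mostly zeros; compare against the direct percentile oracle
        expect = np.percentile(nd[:112], 95) * 100
        assert got == pytest.approx(expect)

    def test_percentile_monotonicity(self, rng):
        nd = rng.uniform(0, 0.5, size=(224, 224))
        p = _patch(ndsm=nd)
        chs = [extract_canopy_height(p, s) for s in ("max", "p99", "p97", "p95")]
        assert chs == sorted(chs, reverse=True)

    def test_single_row_uses_occupied_half(self):
        nd = np.zeros((224, 224))
        nd[50, 100] = 0.30
        got = extract_canopy_height(_patch(ndsm=nd, single_row=True, occupied_half="top"))
        assert got == pytest.approx(30.0)

    def test_cell_bounds_exclude_neighbour_canopy(self):
        nd = np.zeros((224, 224))
        nd[60, 100] = 0.30
        nd[160, 100] = 0.20
        nd[5, 100] = 0.99  # neighbouring bed's canopy inside the crop box
        clipped = extract_canopy_height(_patch(ndsm=nd, cell_y=(21.0, 203.0)))
        assert clipped == pytest.approx(25.0)

    def test_nan_half_falls_back(self):
        nd = np.full((224, 224), np.nan)
        nd[150, 100] = 0.20
        assert extract_canopy_height(_patch(ndsm=nd)) == pytest.approx(20.0)

    def test_unknown_stat_rejected(self):
        with pytest.raises(ValueError):
            extract_canopy_height(_patch(), stat="median")


class TestFuseNdsmRgb:
    def test_zero_ndsm_is_identity(self, rng):
        rgb = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        out = fuse_ndsm_rgb(_patch(rgb=rgb))
        np.testing.assert_array_equal(out, rgb)

    def test_half_meter_adds_fifty(self):
        out = fuse_ndsm_rgb(_patch(ndsm=np.full((224, 224), 0.5)))
        assert (out[..., 1] == 150).all()

    def test_clipping_at_255(self):
        rgb = np.full((224, 224, 3), 200, np.uint8)
        out = fuse_ndsm_rgb(_patch(rgb=rgb, ndsm=np.full((224, 224), 1.0)))
        assert (out[..., 1] == 255).all()

    @settings(deadline=None, max_examples=25)
    @given(
        g=hnp.arrays(np.uint8, (224, 224)),
        nd=hnp.arrays(
            np.float64, (224, 224),
            elements=st.floats(-3, 4, allow_nan=False, allow_infinity=False),
        ),
    )
    def test_formula_on_random_patches(self, g, nd):
        """G' = clip(round(G + 100 * nDSM), 0, 255); R and B untouched."""
        rgb = np.stack([np.full((224, 224), 7, np.uint8), g, np.full((224, 224), 9, np.uint8)], axis=-1)
        out = fuse_ndsm_rgb(_patch(rgb=rgb, ndsm=nd))
        expect = np.clip(np.rint(g.astype(float) + 100 * nd), 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out[..., 1], expect)
        np.testing.assert_array_equal(out[..., 0], rgb[..., 0])
        np.testing.assert_array_equal(out[..., 2], rgb[..., 2])


def _height_separable_patches(rng, n=60, shared_rgb=True):
    """Classes that differ only in canopy height (identical RGB statistics)."""
    yy, xx = np.mgrid[0:224, 0:224]
    r2 = ((xx - 112) / 70) ** 2 + ((yy - 112) / 70) ** 2
    patches, labels = [], []
    for i in range(n):
        cls = i % 2
        rgb = rng.integers(40, 120, size=(224, 224, 3)).astype(np.uint8)
        h = (0.35 if cls == 0 else 0.18) + rng.normal(0, 0.02)
        nd = np.zeros((224, 224))
        nd[r2 < 1] = h * (1 - r2[r2 < 1])
        patches.append(_patch(rgb=rgb, ndsm=nd, plot_id=i))
        labels.append(cls)
    return patches, labels


class TestBuildDataset:
    def test_split_ratio_and_augmentation(self, rng):
        patches, labels = _height_separable_patches(rng, n=100)
        spec = TrainSpec(seed=1)
        xtr, ytr, xte, yte = build_dataset(patches, labels, "rgb", spec)
        assert len(xte) == 20
        assert len(xtr) == 80 * 4  # originals + 3 flip transforms
        assert len(ytr) == len(xtr)

    def test_same_seed_same_membership(self, rng):
        patches, labels = _height_separable_patches(rng, n=40)
        spec = TrainSpec(seed=5)
        _, _, xte1, yte1 = build_dataset(patches, labels, "ndsm", spec)
        _, _, xte2, yte2 = build_dataset(patches, labels, "ndsm", spec)
        np.testing.assert_array_equal(xte1, xte2)
        np.testing.assert_array_equal(yte1, yte2)

    def test_single_class_rejected(self, rng):
        patches, _ = _height_separable_patches(rng, n=10)
        with pytest.raises(ValueError):
            build_dataset(patches, [0] * 10, "rgb", TrainSpec())


class TestTraining:
    def test_grid_has_18_combinations_with_fold_scores(self, rng):
        patches, labels = _height_separable_patches(rng, n=40)
        spec = TrainSpec(modality="ndsm", runs=1, seed=3)
        result = train_trait_classifier(build_dataset(patches, labels, "ndsm", spec), spec)
        assert len(result.cv_table) == 2 * 3 * 3
        fold_cols = [c for c in result.cv_table.columns if c.startswith("fold")]
        assert len(fold_cols) == 5

    def test_height_separable_classes_learned(self, rng):
        patches, labels = _height_separable_patches(rng, n=60)
        spec = TrainSpec(
            modality="ndsm", runs=3, seed=4,
            batch_grid=(16,), epochs_grid=(15,), lr_grid=(1e-3,),
        )
        result = train_trait_classifier(build_dataset(patches, labels, "ndsm", spec), spec)
        assert result.mean_accuracy >= 0.95
        assert len(result.accuracies) == 3
        assert result.sd_accuracy >= 0.0

    def test_evaluate_hand_worked(self, rng):
        patches, labels = _height_separable_patches(rng, n=60)
        spec = TrainSpec(modality="ndsm", runs=1, seed=6,
                         batch_grid=(16,), epochs_grid=(15,), lr_grid=(1e-3,))
        datasets = build_dataset(patches, labels, "ndsm", spec)
        result = train_trait_classifier(datasets, spec)
        acc, r0, r1 = evaluate_trait_classifier(result.model, datasets[2], datasets[3])
        assert 0 <= acc <= 100

    def test_evaluate_empty_test_set_is_error(self, rng):
        patches, labels = _height_separable_patches(rng, n=60)
        spec = TrainSpec(modality="ndsm", runs=1, seed=6,
                         batch_grid=(16,), epochs_grid=(10,), lr_grid=(1e-3,))
        datasets = build_dataset(patches, labels, "ndsm", spec)
        result = train_trait_classifier(datasets, spec)
        with pytest.raises(ValueError):
            evaluate_trait_classifier(result.model, datasets[2][:0], datasets[3][:0])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TrainSpec(model_name="vgg")
        with pytest.raises(ValueError):
            TrainSpec(modality="thermal")
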