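"""Overlap metrics, Hausdorff distance, CV layout, and paired statistics."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from aortamorph import (
    ConfusionCounts,
    LabelVolume,
    ShapeMismatchError,
    ValidationError,
    ZeroVarianceError,
    compute_metrics,
    confusion_counts,
    hausdorff_distance,
    make_cv_layout,
    paired_comparison,
    patient_metrics,
)


def volume_from_points(points, shape, spacing=(1, 1, 1), label=1):
    voxels = np.zeros(shape, int)
    for p in points:
        voxels[tuple(p)] = label
    return LabelVolume(voxels, spacing)


class TestConfusionCounts:
    def test_identity_pair(self):
        rng = np.random.default_rng(0)
        vol = LabelVolume(rng.integers(0, 3, (4, 5, 5)), (1, 1, 1))
        c = confusion_counts(vol, vol, 1)
        assert c.fp == c.fn == 0
        assert c.tp == (vol.voxels == 1).sum()

    def test_empty_prediction(self):
        gt = np.zeros((4, 5, 5), int)
        gt.flat[:10] = 1
        c = confusion_counts(
            LabelVolume(gt, (1, 1, 1)),
            LabelVolume(np.zeros_like(gt), (1, 1, 1)),
            1,
        )
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 90, 0, 10)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        gt = LabelVolume(rng.integers(0, 4, (5, 20, 20)), (1, 1, 1))
        pred = LabelVolume(rng.integers(0, 4, (5, 20, 20)), (1, 1, 1))
        for label in (1, 2):
            tp = tn = fp = fn = 0
            for z in range(5):
                for y in range(20):
                    for x in range(20):
                        g = gt.voxels[z, y, x] == label
                        p = pred.voxels[z, y, x] == label
                        tp += g and p
                        fp += (not g) and p
                        fn += g and (not p)
                        tn += (not g) and (not p)
            c = confusion_counts(gt, pred, label)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_shape_mismatch_reported(self):
        a = LabelVolume(np.zeros((2, 2, 2), int), (1, 1, 1))
        b = LabelVolume(np.zeros((2, 2, 3), int), (1, 1, 1))
        with pytest.raises(ShapeMismatchError, match=r"\(2, 2, 2\).*\(2, 2, 3\)"):
            confusion_counts(a, b, 1)

    def test_spacing_mismatch_reported(self):
        a = LabelVolume(np.zeros((2, 2, 2), int), (1, 1, 1))
        b = LabelVolume(np.zeros((2, 2, 2), int), (1, 1, 2))
        with pytest.raises(ShapeMismatchError, match="spacing"):
            confusion_counts(a, b, 1)


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=8, tn=90, fp=1, fn=1))
        assert m.accuracy == pytest.approx(0.98)
        assert m.precision == pytest.approx(8 / 9)
        assert m.recall == pytest.approx(8 / 9)
        assert m.iou == pytest.approx(0.8)
        assert m.dsc == pytest.approx(8 / 9)

    def test_zero_denominators_are_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=100, fp=0, fn=0))
        assert m.accuracy == 1.0
        assert all(math.isnan(v) for v in (m.precision, m.recall, m.iou, m.dsc))

    def test_dsc_iou_identity_on_random_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 1000, 4)
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert abs(m.dsc - 2 * m.iou / (1 + m.iou)) < 1e-12

    def test_accuracy_at_least_iou_with_tn(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fp, fn = rng.integers(0, 50, 3)
            tn = int(rng.integers(1, 50))
            if tp + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), tn, int(fp), int(fn)))
            assert m.accuracy >= m.iou


class TestHausdorff:
    def test_three_four_five(self):
        a = volume_from_points([(0, 0, 0)], (1, 4, 5))
        b = volume_from_points([(0, 3, 4)], (1, 4, 5))
        assert hausdorff_distance(a, b, 1) == pytest.approx(5.0)

    def test_identity_zero(self):
        rng = np.random.default_rng(4)
        vol = LabelVolume((rng.random((4, 6, 6)) < 0.3).astype(int), (1, 1, 1))
        assert hausdorff_distance(vol, vol, 1) == 0.0

    def test_directed_asymmetry_resolved_by_max(self):
        a = volume_from_points([(0, 0, 0), (0, 0, 10)], (1, 1, 11))
        b = volume_from_points([(0, 0, 0)], (1, 1, 11))
        assert hausdorff_distance(a, b, 1) == pytest.approx(10.0)
        assert hausdorff_distance(b, a, 1) == pytest.approx(10.0)  # symmetric

    def test_absent_label_is_inf_with_warning(self):
        a = volume_from_points([(0, 0, 0)], (2, 2, 2))
        empty = LabelVolume(np.zeros((2, 2, 2), int), (1, 1, 1))
        with pytest.warns(UserWarning, match="absent"):
            assert math.isinf(hausdorff_distance(a, empty, 1))

    def test_spacing_scales_distances(self):
        a = volume_from_points([(0, 0, 0)], (2, 2, 4), spacing=(1, 1, 2.5))
        b = volume_from_points([(0, 0, 3)], (2, 2, 4), spacing=(1, 1, 2.5))
        assert hausdorff_distance(a, b, 1) == pytest.approx(7.5)
        assert hausdorff_distance(a, b, 1, units="voxel") == pytest.approx(3.0)

    def test_full_set_differs_from_boundary_only_on_cavity(self):
        # gt: solid 7x7x7 block; pred: its shell — boundaries coincide, but
        # the solid interior is far from the shell
        solid = np.zeros((9, 9, 9), int)
        solid[1:8, 1:8, 1:8] = 1
        shell = solid.copy()
        shell[2:7, 2:7, 2:7] = 0
        gt = LabelVolume(solid, (1, 1, 1))
        pred = LabelVolume(shell, (1, 1, 1))
        hd = hausdorff_distance(gt, pred, 1)
        # centre voxel (4,4,4) is 3 voxels from the nearest shell voxel;
        # a boundary-only computation would report 0 (outer hulls coincide)
        assert hd == pytest.approx(3.0)

    def test_matches_allpairs_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            shape = (4, 8, 8)
            spacing = tuple(rng.uniform(0.5, 2.0, 3))
            a = (rng.random(shape) < 0.2).astype(int)
            b = (rng.random(shape) < 0.2).astype(int)
            if not a.any() or not b.any():
                continue
            va = LabelVolume(a, spacing)
            vb = LabelVolume(b, spacing)
            pa = np.argwhere(a) * np.asarray(spacing)
            pb = np.argwhere(b) * np.asarray(spacing)
            d = cdist(pa, pb)
            expected = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff_distance(va, vb, 1) == pytest.approx(expected, abs=1e-9)


class TestPatientMetrics:
    def test_perfect_prediction(self, small_phantom):
        _, result = small_phantom
        metrics = patient_metrics(result.annotation, result.annotation)
        for label in (1, 2):
            m = metrics[label]
            assert (
                m.accuracy == m.precision == m.recall == m.iou == m.dsc == 1.0
            )
            assert m.hd == 0.0

    def test_slice_permutation_invariance(self, small_phantom):
        _, result = small_phantom
        rng = np.random.default_rng(6)
        perm = rng.permutation(result.annotation.n_slices)
        gt_p = LabelVolume(result.annotation.voxels[perm], result.annotation.spacing)
        from aortamorph import DegradationSpec, degrade_prediction

        pred = degrade_prediction(
            result.annotation, DegradationSpec(boundary_shift_mm=0.9, seed=8)
        )
        pred_p = LabelVolume(pred.voxels[perm], pred.spacing)
        base = patient_metrics(result.annotation, pred)
        permuted = patient_metrics(gt_p, pred_p)
        for label in (1, 2):
            for name, value in base[label].as_dict().items():
                assert value == pytest.approx(
                    getattr(permuted[label], name), abs=1e-12
                )

    def test_swap_symmetry_precision_recall(self, small_phantom):
        _, result = small_phantom
        from aortamorph import DegradationSpec, degrade_prediction

        pred = degrade_prediction(
            result.annotation, DegradationSpec(boundary_shift_mm=1.2, seed=3)
        )
        for label in (1, 2):
            fwd = compute_metrics(confusion_counts(result.annotation, pred, label))
            rev = compute_metrics(confusion_counts(pred, result.annotation, label))
            assert fwd.precision == pytest.approx(rev.recall)
            assert fwd.recall == pytest.approx(rev.precision)


class TestCVLayout:
    def test_24_patients_4_folds_of_6(self):
        layout = make_cv_layout([f"P{i}" for i in range(24)], k=4, seed=1)
        assert sorted(len(f) for f in layout.folds()) == [6, 6, 6, 6]

    def test_pigeonhole_sizes(self):
        layout = make_cv_layout(list("abcde"), k=4, seed=1)
        assert sorted(len(f) for f in layout.folds()) == [1, 1, 1, 2]

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(24)]
        assert (
            make_cv_layout(ids, 4, seed=9).fold_assignment
            == make_cv_layout(ids, 4, seed=9).fold_assignment
        )

    def test_partition_property(self):
        ids = [f"P{i}" for i in range(10)]
        layout = make_cv_layout(ids, k=3, seed=2)
        assert sorted(sum(layout.folds(), [])) == sorted(ids)

    def test_too_many_folds(self):
        with pytest.raises(ValidationError):
            make_cv_layout(["a", "b"], k=4)


class TestPairedComparison:
    def test_identical_series_zero_variance(self):
        vals = np.arange(10, dtype=float)
        with pytest.raises(ZeroVarianceError):
            paired_comparison(vals, vals)

    def test_symmetric_differences_give_t_zero(self):
        b = np.zeros(5)
        a = np.array([-1.0, 0.0, 1.0, -2.0, 2.0])
        cmp = paired_comparison(a, b)
        assert cmp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.t_p == pytest.approx(1.0)

    def test_shapiro_matches_reference_implementation(self):
        # W for this sample computed once with R 4.3.3 shapiro.test
        x = np.array([4.1, 5.2, 3.8, 6.0, 5.5, 4.9, 7.2, 3.3, 5.8, 4.4, 6.5, 5.1])
        cmp = paired_comparison(x, np.zeros_like(x))
        assert cmp.shapiro_w == pytest.approx(0.9904413380, abs=1e-3)

    def test_t_matches_reference_implementation(self):
        # t and p computed once with R 4.3.3 t.test on the same differences
        d = np.array(
            [0.12, -0.55, 1.30, 0.02, -0.81, 0.44, 0.97, -1.22, 0.31, -0.08,
             0.66, -0.37, 1.05, -0.91, 0.23, 0.58, -1.44, 0.77, 0.05, -0.29,
             1.88, -0.63, 0.41, 0.15]
        )
        cmp = paired_comparison(d, np.zeros_like(d))
        assert cmp.t_statistic == pytest.approx(0.6702982433, abs=1e-6)
        assert cmp.t_p == pytest.approx(0.5093426575, abs=1e-6)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            paired_comparison([1.0, 2.0], [0.0, 1.0])

    def test_nan_pairs_dropped(self):
        a = np.array([1.0, np.nan, 3.0, 2.5, 4.0])
        b = np.array([0.5, 1.0, 2.0, np.nan, 3.0])
        cmp = paired_comparison(a, b)
        assert len(cmp.differences) == 3


class TestMetricProperties:
    """Seeded property tests over randomly generated confusion counts."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts = st.integers(min_value=0, max_value=10**6)

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_bounds_and_dsc_iou_identity(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        for value in (m.accuracy, m.precision, m.recall, m.iou, m.dsc):
            assert math.isnan(value) or 0.0 <= value <= 1.0
        if not math.isnan(m.iou):
            assert abs(m.dsc - 2 * m.iou / (1 + m.iou)) < 1e-12
        if tn > 0 and not math.isnan(m.iou):
            assert m.accuracy >= m.iou
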