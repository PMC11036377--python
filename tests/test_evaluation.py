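"""Evaluation metrics and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from neosynth.evaluation import (EvalRecord, age_binned_summary,
                                 average_surface_distance,
                                 consistency_dice, dice_score,
                                 flag_outliers, merge_for_eval,
                                 records_to_frame, volume_correlation)


def _cube(n, lo, hi):
    m = np.zeros((n, n, n), bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return m


class TestDice:
    def test_identical_masks(self):
        m = _cube(8, 2, 6)
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        assert dice_score(_cube(8, 0, 3), _cube(8, 5, 8)) == 0.0

    def test_hand_case_half(self):
        a = np.zeros((4, 1, 1), bool)
        b = np.zeros((4, 1, 1), bool)
        a[:2] = True        # |X| = 2
        b[1:3] = True       # |Y| = 2, overlap 1
        assert dice_score(a, b) == pytest.approx(0.5)

    def test_empty_conventions(self):
        empty = np.zeros((4, 4, 4), bool)
        assert dice_score(empty, empty) == 1.0
        assert dice_score(empty, _cube(4, 0, 2)) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            dice_score(np.zeros((4, 4, 4), bool), np.zeros((5, 5, 5),
                                                           bool))


class TestMergeForEval:
    def test_ventricles_absorbed_into_csf(self, smooth_phantom):
        _, label_map, _ = smooth_phantom
        merged = merge_for_eval(label_map)
        csf = label_map.id_of("csf")
        expected = label_map.mask("csf") | label_map.mask("ventricles")
        assert np.array_equal(merged.voxels == csf, expected)

    def test_idempotent(self, smooth_phantom):
        _, label_map, _ = smooth_phantom
        once = merge_for_eval(label_map)
        twice = merge_for_eval(once)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_merged_dice_at_least_min_of_parts(self, smooth_phantom):
        """Merging CSF+ventricles cannot drop the dice below the worse of
        the two separate scores (nested-mask construction)."""
        _, gt, _ = smooth_phantom
        pred = gt.with_voxels(np.roll(gt.voxels, 1, axis=0))
        d_csf = dice_score(pred.mask("csf"), gt.mask("csf"))
        d_ven = dice_score(pred.mask("ventricles"), gt.mask("ventricles"))
        pm, gm = merge_for_eval(pred), merge_for_eval(gt)
        d_merged = dice_score(pm.mask("csf+ventricles"),
                              gm.mask("csf+ventricles"))
        assert d_merged >= min(d_csf, d_ven)


class TestAverageSurfaceDistance:
    def test_identical_masks_zero(self):
        m = _cube(10, 3, 7)
        assert average_surface_distance(m, m) == 0.0

    def test_offset_cubes_match_brute_force(self):
        """Exact agreement with the all-pairs boundary computation."""
        a = _cube(12, 3, 7)
        b = np.roll(a, 1, axis=0)
        asd = average_surface_distance(a, b)

        def boundary(mask):
            er = ndimage.binary_erosion(
                mask, structure=ndimage.generate_binary_structure(3, 1),
                border_value=0)
            return np.argwhere(mask & ~er)

        pa, pb = boundary(a), boundary(b)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        brute = np.concatenate([d.min(axis=1), d.min(axis=0)]).mean()
        assert asd == pytest.approx(brute, abs=1e-12)

    def test_voxel_size_scales_linearly(self):
        a = _cube(12, 3, 7)
        b = np.roll(a, 2, axis=1)
        asd1 = average_surface_distance(a, b, (1.0, 1.0, 1.0))
        asd2 = average_surface_distance(a, b, (2.0, 2.0, 2.0))
        assert asd2 == pytest.approx(2 * asd1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_surface_distance(np.zeros((4, 4, 4), bool),
                                     _cube(4, 0, 2))


class TestVolumeCorrelation:
    def test_identity_relation(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        r, slope = volume_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_five_percent_offset(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        r, slope = volume_correlation(a, 1.05 * a)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.05)

    def test_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0])
        r, _ = volume_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            volume_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            volume_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _records(ages_dices):
    return [EvalRecord(subject_id=f"s{i}", model_id="m",
                       structure="gm", dice=d, age_weeks=a)
            for i, (a, d) in enumerate(ages_dices)]


class TestAgeBins:
    def test_one_record_per_bin(self):
        recs = _records([(30, 0.9), (33, 0.8), (37, 0.7), (41, 0.6)])
        summary = age_binned_summary(recs)
        assert list(summary.n) == [1, 1, 1, 1]

    def test_boundary_goes_to_upper_bin(self):
        recs = _records([(32, 0.9)] + [(27, 0.5)] * 4)
        summary = age_binned_summary(recs)
        assert summary.loc[1, "n"] == 1  # [32, 36)
        assert summary.loc[0, "n"] == 4

    def test_means_match_hand_computation(self):
        recs = _records([(27, 0.2), (28, 0.4), (33, 0.6), (34, 0.8),
                         (38, 0.5), (44, 0.9)])
        summary = age_binned_summary(recs)
        assert summary.loc[0, "mean_dice"] == pytest.approx(0.3)
        assert summary.loc[1, "mean_dice"] == pytest.approx(0.7)
        assert summary.loc[2, "mean_dice"] == pytest.approx(0.5)
        assert summary.loc[3, "mean_dice"] == pytest.approx(0.9)

    def test_out_of_range_excluded_with_warning(self):
        recs = _records([(20, 0.5), (30, 0.6)])
        with pytest.warns(RuntimeWarning, match="excluding"):
            summary = age_binned_summary(recs)
        assert summary.n.sum() == 1


class TestOutliers:
    def test_all_equal_no_outliers(self):
        recs = _records([(30, 0.8)] * 6)
        assert flag_outliers(recs) == []

    def test_single_low_subject_flagged(self):
        # a large cohort of tight scores plus one collapse: the deviant
        # subject exceeds 3 cohort standard deviations
        good = [(30 + i, 0.90 + 0.01 * (i % 3)) for i in range(14)]
        recs = _records(good + [(44, 0.30)])
        assert flag_outliers(recs, k=3) == ["s14"]

    def test_infinite_k_empty(self):
        recs = _records([(30, 0.1), (31, 0.9), (32, 0.5), (33, 0.7),
                         (34, 0.3)])
        assert flag_outliers(recs, k=np.inf) == []

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            flag_outliers(_records([(30, 0.5)] * 3))


class TestConsistency:
    def test_identical_predictions(self, smooth_phantom):
        _, label_map, _ = smooth_phantom
        assert consistency_dice(label_map, label_map, "gm") == 1.0

    def test_symmetric(self, smooth_phantom):
        _, a, _ = smooth_phantom
        b = a.with_voxels(np.roll(a.voxels, 1, axis=2))
        assert consistency_dice(a, b, "gm") == consistency_dice(b, a,
                                                                "gm")

    def test_delegates_to_dice(self, smooth_phantom):
        _, a, _ = smooth_phantom
        b = a.with_voxels(np.roll(a.voxels, 1, axis=2))
        assert consistency_dice(a, b, "wm") == dice_score(a.mask("wm"),
                                                          b.mask("wm"))


def test_dice_and_asd_rank_perturbations_consistently(smooth_phantom):
    """Growing erosion of a mask lowers dice and raises ASD monotonically,
    so the two metrics agree in ranking."""
    _, label_map, _ = smooth_phantom
    gt = label_map.mask("wm")
    dices, asds = [], []
    for it in (1, 2, 3):
        pred = ndimage.binary_erosion(gt, iterations=it)
        dices.append(dice_score(pred, gt))
        asds.append(average_surface_distance(pred, gt))
    assert dices[0] > dices[1] > dices[2]
    assert asds[0] < asds[1] < asds[2]


def test_records_roundtrip_frame():
    recs = _records([(30, 0.9), (31, 0.8)])
    df = records_to_frame(recs)
    assert isinstance(df, pd.DataFrame)
    assert set(df.columns) >= {"subject_id", "model_id", "structure",
                               "dice", "age_weeks"}
    with pytest.raises(ValueError):
        EvalRecord("s", "m", "gm", dice=1.2)
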