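"""Slice metrics, distance binning, rank tests, accuracy colormaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vctdbt.evaluation import (SliceRecord, accuracy_colormap, bin_by_distance,
                               compare_models, confusion_per_slice,
                               improvement, metrics, slice_distance)
from vctdbt.phantom import LabelVolume


def _vol(labels):
    return LabelVolume(np.asarray(labels, np.uint8), voxel_mm=0.5)


class TestSliceDistance:
    def test_central_slice_zero(self):
        assert slice_distance(49, 100, 0.5) == 0.0  # even count: centre at 49
        assert slice_distance(50, 101, 0.5) == 0.0

    def test_bottom_slice_of_hundred(self):
        """100 slices at 0.5 mm: slice 0 sits at (0-49)*0.5 = -24.5 mm."""
        assert slice_distance(0, 100, 0.5) == pytest.approx(-24.5)

    def test_strictly_increasing_in_z(self):
        d = [slice_distance(z, 30, 1.0) for z in range(30)]
        assert np.all(np.diff(d) > 0)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            slice_distance(0, 0, 1.0)


class TestConfusionPerSlice:
    def test_perfect_prediction_no_errors(self, rng):
        truth = _vol(rng.integers(0, 3, (8, 8, 3)))
        rec = confusion_per_slice(truth, truth, 1)
        for c in range(3):
            tp, fp, fn, tn = rec.counts[c]
            assert fp == 0 and fn == 0

    def test_class_swap_symmetry(self, rng):
        labels = rng.integers(0, 3, (8, 8, 1)).astype(np.uint8)
        swapped = labels.copy()
        swapped[labels == 1] = 2
        swapped[labels == 2] = 1
        rec = confusion_per_slice(_vol(swapped), _vol(labels), 0)
        assert rec.counts[1][1] == rec.counts[2][2]  # class-1 FP = class-2 FN

    def test_matches_exhaustive_tally(self, rng):
        pred = rng.integers(0, 3, (8, 8, 1)).astype(np.uint8)
        truth = rng.integers(0, 3, (8, 8, 1)).astype(np.uint8)
        rec = confusion_per_slice(_vol(pred), _vol(truth), 0)
        for c in range(3):
            tp = sum(1 for i in range(8) for j in range(8)
                     if pred[i, j, 0] == c and truth[i, j, 0] == c)
            fp = sum(1 for i in range(8) for j in range(8)
                     if pred[i, j, 0] == c and truth[i, j, 0] != c)
            fn = sum(1 for i in range(8) for j in range(8)
                     if pred[i, j, 0] != c and truth[i, j, 0] == c)
            assert rec.counts[c][:3] == (tp, fp, fn)

    def test_counts_conserve_pixels(self, rng):
        pred = _vol(rng.integers(0, 3, (6, 7, 2)))
        truth = _vol(rng.integers(0, 3, (6, 7, 2)))
        rec = confusion_per_slice(pred, truth, 1)
        for c in range(3):
            assert sum(rec.counts[c]) == 42

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            confusion_per_slice(_vol(np.zeros((4, 4, 2))),
                                _vol(np.zeros((4, 5, 2))), 0)


class TestMetrics:
    def _record(self, tp, fp, fn, tn):
        return SliceRecord(0, "m", 0, 0.0, {0: (tp, fp, fn, tn)})

    def test_identical_masks(self):
        m = metrics(self._record(10, 0, 0, 20), 0)
        assert m["jaccard"] == 1.0
        assert m["dice"] == 1.0
        assert m["jaccard_distance"] == 0.0

    def test_disjoint_masks(self):
        m = metrics(self._record(0, 5, 5, 20), 0)
        assert m["jaccard"] == 0.0
        assert m["dice"] == 0.0
        assert m["jaccard_distance"] == 1.0

    def test_jaccard_dice_identity(self, rng):
        """J = D / (2 - D) for any confusion counts."""
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, 3)
            m = metrics(self._record(int(tp), int(fp), int(fn), 10), 0)
            assert m["jaccard"] == pytest.approx(
                m["dice"] / (2 - m["dice"]), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500), tn=st.integers(0, 500))
    def test_metric_bounds_and_identity_for_any_counts(self, tp, fp, fn, tn):
        """For every confusion table: metrics lie in [0,1] and the
        Jaccard-Dice identity holds whenever the union is non-empty."""
        if tp + fp + fn + tn == 0:
            return
        m = metrics(self._record(tp, fp, fn, tn), 0)
        for name, v in m.items():
            assert np.isnan(v) or 0.0 <= v <= 1.0, name
        if tp + fp + fn > 0:
            assert m["jaccard"] == pytest.approx(
                m["dice"] / (2 - m["dice"]), abs=1e-12)
            assert m["jaccard_distance"] == pytest.approx(1 - m["jaccard"])

    def test_empty_union_flagged_nan(self):
        m = metrics(self._record(0, 0, 0, 30), 0)
        assert np.isnan(m["jaccard"])
        assert np.isnan(m["jaccard_distance"])
        assert m["accuracy"] == 1.0


class TestBinByDistance:
    def _records(self, n, rng, model="m"):
        out = []
        for i in range(n):
            counts = {c: tuple(int(v) for v in rng.integers(1, 20, 4))
                      for c in range(3)}
            out.append(SliceRecord(i // 20, model, i % 20,
                                   float(i % 20) - 10.0 + 0.01 * i, counts))
        return out

    def test_hundred_records_ten_equal_bins(self, rng):
        table = bin_by_distance(self._records(100, rng))
        per_bin = table[table["class"] == "air"]["n_slices"]
        assert len(per_bin) == 10
        assert set(per_bin) == {10}

    def test_partition_is_complete(self, rng):
        table = bin_by_distance(self._records(95, rng))
        assert table[table["class"] == "air"]["n_slices"].sum() == 95

    def test_bin_boundaries_at_deciles(self, rng):
        recs = self._records(100, rng)
        table = bin_by_distance(recs)
        d = np.sort([r.d_mm for r in recs])
        air = table[table["class"] == "air"].sort_values("bin")
        expected = [d[b * 10:(b + 1) * 10].mean() for b in range(10)]
        assert np.allclose(air["d_mean_mm"], expected)

    def test_too_few_slices_rejected(self, rng):
        with pytest.raises(ValueError):
            bin_by_distance(self._records(5, rng))


class TestImprovement:
    def test_halving_is_fifty_percent(self):
        assert improvement(0.10, 0.05) == pytest.approx(50.0)

    def test_no_change_zero(self):
        assert improvement(0.2, 0.2) == 0.0

    def test_published_extreme_bin_row(self):
        """Rounded bin means 0.064 -> 0.044 correspond to a ~31% gain."""
        assert improvement(0.064, 0.044) == pytest.approx(31.25, abs=0.01)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            improvement(0.0, 0.1)


class TestCompareModels:
    def test_identical_groups_statistic_zero(self):
        out = compare_models({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert out["kruskal_h"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_rank_sum_p_point_one(self):
        """{1,2,3} vs {4,5,6}: two-sided exact p = 2/20 = 0.1."""
        out = compare_models({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert out["pairwise_p"][("a", "b")] == pytest.approx(0.1)

    def test_p_values_in_unit_interval(self, rng):
        groups = {m: rng.normal(size=30) for m in "abc"}
        out = compare_models(groups)
        assert 0 <= out["kruskal_p"] <= 1
        for p in out["pairwise_p"].values():
            assert 0 <= p <= 1

    def test_holm_correction_monotone(self, rng):
        groups = {m: rng.normal(loc=i, size=15) for i, m in enumerate("abc")}
        raw = compare_models(groups)["pairwise_p"]
        adj = compare_models(groups, holm=True)["pairwise_p"]
        for k in raw:
            assert adj[k] >= raw[k] - 1e-12

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": [1.0], "b": [1, 2, 3]})


class TestAccuracyColormap:
    def test_perfect_prediction_no_error_colors(self, rng):
        truth = _vol(rng.integers(0, 3, (6, 6, 1)))
        img, counts = accuracy_colormap(truth, truth, 0)
        assert counts["red"] == 0
        assert counts["yellow"] == 0

    def test_all_air_truth_all_adipose_pred_fully_red(self):
        truth = _vol(np.zeros((5, 5, 1)))
        pred = _vol(np.ones((5, 5, 1)))
        img, counts = accuracy_colormap(pred, truth, 0)
        assert counts["red"] == 25
        assert np.all(img == np.array([255, 0, 0], np.uint8))

    def test_category_counts_match_confusion(self, rng):
        pred = _vol(rng.integers(0, 3, (10, 10, 1)))
        truth = _vol(rng.integers(0, 3, (10, 10, 1)))
        img, counts = accuracy_colormap(pred, truth, 0)
        rec = confusion_per_slice(pred, truth, 0)
        air_tp = rec.counts[0][0]
        air_errors = rec.counts[0][1] + rec.counts[0][2]  # FP + FN of air
        assert counts["blue"] == air_tp
        assert counts["red"] == air_errors
        assert sum(counts.values()) == 100
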