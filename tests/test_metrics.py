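"""Region derivation and segmentation metrics, including an exhaustive
Hausdorff oracle and the DSC↔IoU algebraic identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainseg import metrics as M


class TestRegionMasks:
    def test_all_background_gives_empty_masks(self):
        masks = M.region_masks(np.zeros((4, 4), int))
        assert not masks.WT.any() and not masks.TC.any() and not masks.EnT.any()

    def test_one_pixel_per_class_counts(self):
        labels = np.zeros((4, 4), int)
        labels[0, 0], labels[1, 1], labels[2, 2] = 1, 2, 3
        masks = M.region_masks(labels)
        assert masks.WT.sum() == 3 and masks.TC.sum() == 2 and masks.EnT.sum() == 1

    def test_file_coding_uses_label_4(self):
        labels = np.zeros((3, 3), int)
        labels[1, 1] = 4
        masks = M.region_masks(labels, coding="file")
        assert masks.EnT.sum() == 1 and masks.TC.sum() == 1 and masks.WT.sum() == 1

    def test_nesting_holds_for_random_maps(self, rng):
        labels = rng.integers(0, 4, (16, 16))
        masks = M.region_masks(labels)
        assert (masks.EnT <= masks.TC).all() and (masks.TC <= masks.WT).all()

    def test_unexpected_value_rejected(self):
        with pytest.raises(ValueError, match="unexpected"):
            M.region_masks(np.array([[5]]))


class TestOverlapScores:
    def test_identical_nonempty_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert M.dsc(m, m) == 1.0 and M.iou(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert M.dsc(a, b) == 0.0 and M.iou(a, b) == 0.0

    def test_hand_counted_example(self):
        # |G| = 4, |S| = 4, overlap 2 -> DSC 0.5
        G = np.zeros((4, 4), bool)
        S = np.zeros((4, 4), bool)
        G[0, :4] = True
        S[0, 2:] = S[1, :2] = True
        assert M.dsc(G, S) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        empty = np.zeros((4, 4), bool)
        assert M.dsc(empty, empty) == 1.0 and M.iou(empty, empty) == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_iou_dsc_identity(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.random((12, 12)) > 0.6
        S = rng.random((12, 12)) > 0.6
        d, j = M.dsc(G, S), M.iou(G, S)
        assert abs(j - d / (2.0 - d)) < 1e-9
        assert d >= j - 1e-12

    def test_published_operating_point_satisfies_identity(self):
        """A whole-tumor DSC of 0.8741 corresponds to IoU 0.7764."""
        d = 0.8741
        assert d / (2 - d) == pytest.approx(0.7764, abs=5e-5)


def _hd95_oracle(T, P, percentile=95.0):
    """Exhaustive pairwise-distance evaluation on boundary points."""
    bt = M.boundary_points(T).astype(float)
    bp = M.boundary_points(P).astype(float)
    d = np.sqrt(((bt[:, None, :] - bp[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(axis=1), percentile),
               np.percentile(d.min(axis=0), percentile))


class TestHausdorff95:
    def test_identical_masks_give_zero(self, rng):
        m = rng.random((10, 10)) > 0.5
        m[0, 0] = True
        assert M.hausdorff95(m, m) == 0.0

    def test_both_empty_convention(self):
        empty = np.zeros((5, 5), bool)
        assert M.hausdorff95(empty, empty) == 0.0

    def test_one_empty_is_undefined(self):
        empty = np.zeros((5, 5), bool)
        full = ~empty
        assert np.isnan(M.hausdorff95(empty, full))

    def test_single_pixels_at_3_4_offset(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert M.hausdorff95(a, b) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[0, 1] = True
        assert M.hausdorff95(a, b, spacing=(1.0, 2.5)) == pytest.approx(2.5)

    def test_symmetric(self, rng):
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        a[5, 5] = b[6, 6] = True
        assert M.hausdorff95(a, b) == pytest.approx(M.hausdorff95(b, a))

    def test_matches_exhaustive_oracle_on_random_masks(self):
        """100 random mask pairs up to 16×16, full pairwise enumeration."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            size = int(rng.integers(4, 17))
            T = rng.random((size, size)) > rng.uniform(0.3, 0.8)
            P = rng.random((size, size)) > rng.uniform(0.3, 0.8)
            if not T.any() or not P.any():
                continue
            assert M.hausdorff95(T, P) == pytest.approx(_hd95_oracle(T, P), abs=1e-9)
            checked += 1

    def test_sup_inf_reading_is_the_100th_percentile(self, rng):
        """The worst-case (maximum) form equals the percentile form at 100."""
        T = rng.random((10, 10)) > 0.5
        P = rng.random((10, 10)) > 0.5
        T[0, 0] = P[9, 9] = True
        assert M.hausdorff95(T, P, percentile=100) == pytest.approx(
            _hd95_oracle(T, P, percentile=100))


class TestPixelMetrics:
    def test_perfect_prediction(self, rng):
        m = rng.random((10, 10)) > 0.5
        pm = M.pixel_metrics(m, m)
        assert (pm.accuracy, pm.precision, pm.recall, pm.f1) == (1, 1, 1, 1)

    def test_confusion_table_arithmetic(self):
        # 10×10 field, |G| = 20, |S| = 25, TP = 15
        G = np.zeros(100, bool)
        S = np.zeros(100, bool)
        G[:20] = True
        S[:15] = S[20:30] = True
        pm = M.pixel_metrics(G.reshape(10, 10), S.reshape(10, 10))
        assert pm.precision == pytest.approx(0.6)
        assert pm.recall == pytest.approx(0.75)
        assert pm.f1 == pytest.approx(2 * 0.45 / 1.35)
        assert pm.accuracy == pytest.approx(0.85)

    def test_f1_is_harmonic_mean(self, rng):
        G = rng.random((10, 10)) > 0.4
        S = rng.random((10, 10)) > 0.4
        pm = M.pixel_metrics(G, S)
        if pm.precision + pm.recall > 0:
            assert pm.f1 == pytest.approx(
                2 * pm.precision * pm.recall / (pm.precision + pm.recall))

    def test_zero_denominator_flagged(self):
        empty = np.zeros((4, 4), bool)
        pm = M.pixel_metrics(empty, empty)
        assert pm.degenerate and pm.precision == 0.0


class TestEvaluateSplit:
    class _IdentityOracle:
        """Feeds the ground truth back as the prediction."""

        def __init__(self, pairs):
            self._labels = iter([seg.labels for _, seg in pairs])

        def predict_labels(self, x):
            return next(self._labels)[None]

    def test_identity_model_scores_perfectly(self, tiny_pairs):
        summary = M.evaluate_split(self._IdentityOracle(tiny_pairs), tiny_pairs)
        for region in M.REGIONS:
            assert summary[region]["dsc"] == 1.0
            assert summary[region]["iou"] == 1.0
            assert summary[region]["hd95"] == 0.0

    def test_report_schema_and_ranges(self, tiny_pairs):
        summary = M.evaluate_split(self._IdentityOracle(tiny_pairs), tiny_pairs)
        assert summary["n_cases"] == len(tiny_pairs)
        for region in M.REGIONS:
            assert set(summary[region]) == set(M.METRIC_NAMES)
            for name in M.METRIC_NAMES:
                value = summary[region][name]
                if name != "hd95":
                    assert 0.0 <= value <= 1.0

    def test_nan_hd95_excluded_from_aggregation(self):
        reports = [
            {r: {m: (np.nan if m == "hd95" else 0.5) for m in M.METRIC_NAMES}
             for r in M.REGIONS},
            {r: {m: (3.0 if m == "hd95" else 0.5) for m in M.METRIC_NAMES}
             for r in M.REGIONS},
        ]
        agg = M.aggregate_reports(reports)
        assert agg["WT"]["hd95"] == 3.0


def test_shrinking_prediction_toward_truth_raises_dsc():
    """On nested masks, trimming false positives weakly increases dice."""
    G = np.zeros((12, 12), bool)
    G[4:8, 4:8] = True
    scores = []
    for margin in (4, 3, 2, 1, 0):
        S = np.zeros((12, 12), bool)
        S[4 - margin:8 + margin, 4 - margin:8 + margin] = True
        scores.append(M.dsc(G, S))
    assert all(a <= b for a, b in zip(scores, scores[1:]))
    assert scores[-1] == 1.0
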