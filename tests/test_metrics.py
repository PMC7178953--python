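"""Contour metrics: worked examples, brute-force oracle agreement, and the
symmetry/ordering/invariance properties the measures must satisfy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tendonseg import metrics

from oracles import (brute_chd, brute_contour, brute_dsc, brute_hausdorff,
                     brute_mad, brute_yasnoff, random_blob_mask)


def square(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + h, c0:c0 + w] = True
    return m


class TestDsc:
    def test_identical_masks_give_one(self):
        m = square((10, 10), 2, 2, 4, 4)
        assert metrics.dsc(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = square((10, 10), 0, 0, 3, 3)
        b = square((10, 10), 6, 6, 3, 3)
        assert metrics.dsc(a, b) == 0.0

    def test_half_overlap(self):
        # |X| = 4, |Y| = 4, overlap 2 -> 2*2/8 = 0.5
        a = square((8, 8), 2, 2, 2, 2)
        b = square((8, 8), 2, 3, 2, 2)
        assert metrics.dsc(a, b) == 0.5

    def test_empty_prediction_gives_zero(self):
        truth = square((8, 8), 2, 2, 3, 3)
        assert metrics.dsc(np.zeros((8, 8), bool), truth) == 0.0

    def test_errors(self):
        m = square((8, 8), 2, 2, 3, 3)
        with pytest.raises(ValueError, match="shape mismatch"):
            metrics.dsc(m, square((9, 9), 2, 2, 3, 3))
        with pytest.raises(ValueError, match="both masks empty"):
            metrics.dsc(np.zeros((8, 8), bool), np.zeros((8, 8), bool))


class TestExtractContour:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        assert metrics.extract_contour(m).tolist() == [[2, 3]]

    def test_filled_square_excludes_centre(self):
        m = square((7, 7), 1, 1, 3, 3)
        pts = {tuple(p) for p in metrics.extract_contour(m)}
        assert len(pts) == 8 and (2, 2) not in pts

    def test_line_is_all_contour(self):
        m = square((5, 9), 2, 1, 1, 6)
        assert len(metrics.extract_contour(m)) == 6

    def test_border_pixels_are_contour(self):
        # a mask filling the whole image: outside counts as background
        m = np.ones((4, 6), bool)
        assert len(metrics.extract_contour(m)) == 2 * 4 + 2 * 6 - 4

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            metrics.extract_contour(np.zeros((4, 4), bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = random_blob_mask(rng, (24, 24))
        got = {tuple(p) for p in metrics.extract_contour(m)}
        want = {tuple(map(int, p)) for p in brute_contour(m)}
        assert got == want


class TestContourDistances:
    def test_identical_contours_zero(self):
        a = metrics.extract_contour(square((9, 9), 2, 2, 4, 4))
        assert metrics.mad(a, a) == 0.0
        assert metrics.hausdorff(a, a) == 0.0

    def test_single_points_five_apart(self):
        a, b = np.array([[0, 0]]), np.array([[3, 4]])
        assert metrics.mad(a, b) == 5.0
        assert metrics.hausdorff(a, b) == 5.0

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_agreement_random_contours(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 30, size=(10, 2))
        b = rng.integers(0, 30, size=(13, 2))
        assert metrics.mad(a, b) == pytest.approx(brute_mad(a, b), abs=1e-9)
        assert metrics.hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_max_ge_mean(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.integers(0, 40, size=(12, 2))
        b = rng.integers(0, 40, size=(9, 2))
        assert metrics.mad(a, b) == pytest.approx(metrics.mad(b, a), abs=1e-12)
        assert metrics.hausdorff(a, b) == pytest.approx(metrics.hausdorff(b, a), abs=1e-12)
        assert metrics.hausdorff(a, b) >= metrics.mad(a, b)

    def test_empty_contour_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            metrics.mad(np.empty((0, 2)), np.array([[1, 1]]))


class TestYasnoff:
    def test_zero_for_identical(self):
        a = metrics.extract_contour(square((9, 9), 1, 1, 5, 5))
        assert metrics.yasnoff(a, a, 81) == 0.0

    def test_closed_form_single_point(self):
        # one point at distance 3, W = 100 -> 100/100 * sqrt(9) = 3
        assert metrics.yasnoff(np.array([[0, 0]]), np.array([[0, 3]]), 100) == \
            pytest.approx(3.0, abs=1e-12)

    def test_doubling_w_halves(self):
        a = np.array([[0, 0], [1, 1]])
        b = np.array([[4, 4]])
        assert metrics.yasnoff(a, b, 200) == pytest.approx(
            metrics.yasnoff(a, b, 100) / 2, abs=1e-12)

    def test_asymmetric_in_arguments(self):
        a = np.array([[0, 0], [0, 10]])
        b = np.array([[0, 0]])
        assert metrics.yasnoff(a, b, 50) != metrics.yasnoff(b, a, 50)

    def test_invalid_w_raises(self):
        with pytest.raises(ValueError, match="positive"):
            metrics.yasnoff(np.array([[0, 0]]), np.array([[1, 1]]), 0)


class TestChd:
    def test_convex_rectangle_near_zero(self):
        m = square((30, 40), 5, 5, 18, 28)
        assert metrics.chd(m) <= 1.0

    def test_notch_depth_recovered(self):
        m = square((40, 60), 0, 0, 40, 60)
        m[0:10, 26:34] = False  # 10-px-deep notch
        assert metrics.chd(m) == pytest.approx(10.0, abs=1.0)

    def test_monotone_in_notch_depth(self):
        vals = []
        for depth in (2, 4, 8):
            m = square((40, 60), 0, 0, 40, 60)
            m[0:depth, 26:34] = False
            vals.append(metrics.chd(m))
        assert vals[0] <= vals[1] <= vals[2]

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_agreement_random_blobs(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = random_blob_mask(rng, (28, 28), n_blobs=(1, 1), radius=(4, 9))
        assert metrics.chd(m) == pytest.approx(brute_chd(m), abs=1.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="empty"):
            metrics.chd(np.zeros((5, 5), bool))


class TestFilterArtifacts:
    def test_keeps_largest_component(self):
        m = square((20, 20), 1, 1, 10, 10)  # 100 px
        m[15, 15] = m[15, 16] = m[16, 15] = True  # 3-px speck
        out = metrics.filter_artifacts(m)
        assert out.sum() == 100 and not out[15, 15]

    def test_single_component_unchanged(self):
        m = square((10, 10), 2, 2, 5, 5)
        assert (metrics.filter_artifacts(m) == m).all()

    def test_size_tie_keeps_first_component_deterministically(self):
        m = np.zeros((10, 10), bool)
        m[1:3, 1:3] = True   # label 1 in scan order
        m[6:8, 6:8] = True   # label 2, same size
        out1 = metrics.filter_artifacts(m)
        out2 = metrics.filter_artifacts(m)
        assert out1[1, 1] and not out1[6, 6]
        assert (out1 == out2).all()

    def test_diagonal_touch_counts_as_connected(self):
        m = np.zeros((6, 6), bool)
        m[1, 1] = m[2, 2] = m[3, 3] = True  # 8-connected chain
        assert metrics.filter_artifacts(m).sum() == 3


class TestEvaluatePair:
    def test_perfect_prediction(self):
        truth = square((30, 40), 5, 5, 15, 25)
        rep = metrics.evaluate_pair(truth, truth)
        assert rep.dsc == 1.0 and rep.mad == 0.0 and rep.hd == 0.0
        assert rep.yasnoff == 0.0
        assert rep.chd == pytest.approx(metrics.chd(truth), abs=1e-12)

    def test_artifact_changes_only_unfiltered_measures(self):
        truth = square((40, 50), 8, 8, 20, 30)
        pred = square((40, 50), 9, 9, 20, 30)
        noisy = pred.copy()
        noisy[2, 45] = True  # isolated 1-px artifact
        clean_rep = metrics.evaluate_pair(pred, truth)
        noisy_rep = metrics.evaluate_pair(noisy, truth)
        assert noisy_rep.hd == clean_rep.hd
        assert noisy_rep.chd == clean_rep.chd
        assert noisy_rep.dsc != clean_rep.dsc

    def test_empty_prediction_flagged(self):
        truth = square((10, 10), 2, 2, 4, 4)
        rep = metrics.evaluate_pair(np.zeros((10, 10), bool), truth)
        assert rep.dsc == 0.0 and rep.pred_empty
        assert np.isnan(rep.mad) and np.isnan(rep.chd)

    def test_batch_summary_rows_are_means(self):
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(4):
            t = random_blob_mask(rng, (24, 24))
            p = random_blob_mask(rng, (24, 24))
            pairs.append((p, t))
        df = metrics.evaluate_batch(pairs)
        body = df[~df.image_id.isin(["mean", "std"])]
        mean_row = df[df.image_id == "mean"].iloc[0]
        for col in ("dsc", "mad", "hd", "yasnoff", "chd"):
            assert mean_row[col] == pytest.approx(body[col].mean(), abs=1e-12)


contours = hnp.arrays(np.int64, st.tuples(st.integers(1, 12), st.just(2)),
                      elements=st.integers(0, 30))


class TestPropertyBased:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=contours, b=contours)
    def test_distance_metric_relations(self, a, b):
        """mad and hausdorff are symmetric, non-negative, bounded by each
        other, and zero exactly when the point sets coincide."""
        m = metrics.mad(a, b)
        h = metrics.hausdorff(a, b)
        assert 0.0 <= m <= h
        assert m == pytest.approx(metrics.mad(b, a), abs=1e-12)
        assert h == pytest.approx(metrics.hausdorff(b, a), abs=1e-12)
        same = {tuple(p) for p in a} == {tuple(p) for p in b}
        assert (h == 0.0) == same

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(mask=hnp.arrays(bool, st.tuples(st.integers(2, 16),
                                           st.integers(2, 16))))
    def test_dsc_bounds_and_contour_membership(self, mask):
        if not mask.any():
            return
        assert metrics.dsc(mask, mask) == 1.0
        pts = metrics.extract_contour(mask)
        assert all(mask[r, c] for r, c in pts)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(300 + seed)
        p = random_blob_mask(rng, (20, 20), radius=(2, 5))
        t = random_blob_mask(rng, (20, 20), radius=(2, 5))
        big_p = np.zeros((40, 40), bool)
        big_t = np.zeros((40, 40), bool)
        big_p[3:23, 3:23] = p
        big_t[3:23, 3:23] = t
        shifted_p = np.roll(np.roll(big_p, 7, axis=0), 5, axis=1)
        shifted_t = np.roll(np.roll(big_t, 7, axis=0), 5, axis=1)
        r1 = metrics.evaluate_pair(big_p, big_t)
        r2 = metrics.evaluate_pair(shifted_p, shifted_t)
        for k in ("dsc", "mad", "hd", "yasnoff", "chd"):
            assert r1.as_dict()[k] == pytest.approx(r2.as_dict()[k], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_iff_contours_coincide(self, seed):
        rng = np.random.default_rng(400 + seed)
        a = np.unique(rng.integers(0, 20, size=(8, 2)), axis=0)
        b = a + np.array([1, 0])
        for f in (metrics.mad, metrics.hausdorff):
            assert f(a, a) == 0.0
            assert f(a, b) > 0.0
        assert metrics.yasnoff(a, a, 100) == 0.0
        assert metrics.yasnoff(a, b, 100) > 0.0
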