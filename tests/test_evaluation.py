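import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mitoseg import synthetic
from mitoseg.evaluation import (SHAPE_DESCRIPTORS, average_fold_deviation,
                                dice_coefficient, energy_distance,
                                evaluate_method, fold_deviation, label_mask,
                                match_objects, normalize_energy_distances,
                                shape_descriptors)


def brute_dice(pred, truth):
    """Pixel-enumeration oracle."""
    inter = pt = tt = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        inter += bool(p) and bool(t)
        pt += bool(p)
        tt += bool(t)
    return 1.0 if pt + tt == 0 else 2 * inter / (pt + tt)


class TestDice:
    def test_identical_disjoint_and_partial(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        b = np.zeros((4, 4), bool)
        b[0, :2] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        # |pred|=4, |truth|=2, overlap 2
        pred = np.zeros((4, 4), bool)
        pred[0] = True
        truth = np.zeros((4, 4), bool)
        truth[0, :2] = True
        assert dice_coefficient(pred, truth) == pytest.approx(2 * 2 / 6)

    def test_both_empty_is_perfect(self):
        z = np.zeros((3, 3), bool)
        assert dice_coefficient(z, z) == 1.0

    def test_exhaustive_2x2_masks_match_oracle(self):
        masks = [np.array(bits, bool).reshape(2, 2)
                 for bits in itertools.product([0, 1], repeat=4)]
        for a in masks:
            for b in masks:
                assert dice_coefficient(a, b) == pytest.approx(brute_dice(a, b))
                assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_random_8x8_masks_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.random((8, 8)) < rng.uniform(0.1, 0.9)
            b = rng.random((8, 8)) < rng.uniform(0.1, 0.9)
            assert dice_coefficient(a, b) == pytest.approx(brute_dice(a, b))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMatching:
    def test_identical_labels_all_one_to_one(self):
        mask = np.zeros((20, 20), bool)
        for i in range(3):
            mask[2 + 6 * i: 5 + 6 * i, 2:5] = True
        lab, k = label_mask(mask)
        match = match_objects(lab, lab)
        assert k == 3
        assert len(match.one_to_one) == 3
        assert match.unmatched_gt == () and match.unmatched_pred == ()

    def test_split_prediction_excluded_from_one_to_one(self):
        gt = np.zeros((10, 10), bool)
        gt[4, 1:9] = True
        pred = gt.copy()
        pred[4, 5] = False  # one GT object vs two predicted fragments
        match = match_objects(label_mask(gt)[0], label_mask(pred)[0])
        assert len(match.pairs) == 2
        assert match.one_to_one.empty

    def test_empty_prediction_all_unmatched(self):
        gt = np.zeros((8, 8), bool)
        gt[1:3, 1:3] = True
        gt[5:7, 5:7] = True
        match = match_objects(label_mask(gt)[0], np.zeros((8, 8), int))
        assert match.pairs.empty
        assert match.unmatched_gt == (1, 2)


class TestDescriptors:
    def test_square_geometry(self):
        mask = np.zeros((14, 14), int)
        mask[2:12, 2:12] = 1
        desc = shape_descriptors(label_mask(mask)[0])
        row = desc.iloc[0]
        assert row["area"] == 100
        assert row["solidity"] == 1.0
        assert row["aspect_ratio"] == pytest.approx(1.0)
        assert row["eccentricity"] == pytest.approx(0.0)
        assert row["perimeter"] == pytest.approx(36.0)

    def test_rectangle_more_eccentric_than_square(self):
        sq = np.zeros((14, 14), int)
        sq[2:12, 2:12] = 1
        rect = np.zeros((10, 26), int)
        rect[4:6, 3:23] = 1
        d_sq = shape_descriptors(label_mask(sq)[0]).iloc[0]
        d_rect = shape_descriptors(label_mask(rect)[0]).iloc[0]
        assert d_rect["eccentricity"] > d_sq["eccentricity"]
        assert d_rect["aspect_ratio"] > d_sq["aspect_ratio"]

    def test_moment_oracle_on_random_objects(self):
        # independent re-derivation of eccentricity/aspect from pixel coords
        rng = np.random.default_rng(4)
        for _ in range(10):
            mask = np.zeros((16, 16), int)
            mask[3:13, 3:13] = (rng.random((10, 10)) < 0.6).astype(int)
            lab, k = label_mask(mask)
            if k == 0:
                continue
            desc = shape_descriptors(lab)
            for _, row in desc.iterrows():
                ys, xs = np.nonzero(lab == row["label"])
                assert row["area"] == len(ys)
                a = np.var(ys) + 1 / 12
                c = np.var(xs) + 1 / 12
                b = np.mean((ys - ys.mean()) * (xs - xs.mean()))
                disc = np.sqrt(((a - c) / 2) ** 2 + b ** 2)
                lam1, lam2 = (a + c) / 2 + disc, max((a + c) / 2 - disc, 1e-12)
                assert row["aspect_ratio"] == pytest.approx(np.sqrt(lam1 / lam2))
                assert row["eccentricity"] == pytest.approx(
                    np.sqrt(max(0, 1 - lam2 / lam1)))

    def test_zero_objects_gives_empty_table(self):
        desc = shape_descriptors(np.zeros((5, 5), int))
        assert desc.empty
        assert list(desc.columns) == ["label", *SHAPE_DESCRIPTORS]


class TestFoldDeviation:
    @pytest.mark.parametrize("g,p,expect", [(10, 10, 1.0), (10, 20, 2.0),
                                            (20, 10, 2.0), (3, 7, 7 / 3)])
    def test_symmetric_ratio(self, g, p, expect):
        assert fold_deviation(g, p) == pytest.approx(expect)
        assert fold_deviation(g, p) == fold_deviation(p, g)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fold_deviation(0.0, 1.0)

    def test_average_over_one_to_one_pairs(self):
        gt = np.zeros((20, 20), bool)
        gt[2:6, 2:6] = True     # 4x4 = 16 px
        gt[10:14, 10:14] = True
        pred = gt.copy()
        pred[10:14, 14:18] = True  # double the second object's area
        match = match_objects(label_mask(gt)[0], label_mask(pred)[0])
        gd = shape_descriptors(label_mask(gt)[0])
        pdsc = shape_descriptors(label_mask(pred)[0])
        afd = average_fold_deviation(match, gd, pdsc, "area")
        assert afd == pytest.approx((1.0 + 2.0) / 2)

    def test_no_pairs_gives_missing_not_zero(self):
        gt = np.zeros((5, 5), bool)
        gt[1:3, 1:3] = True
        match = match_objects(label_mask(gt)[0], np.zeros((5, 5), int))
        gd = shape_descriptors(label_mask(gt)[0])
        assert np.isnan(average_fold_deviation(match, gd, gd, "area"))


class TestEnergyDistance:
    def test_identical_and_singleton(self):
        assert energy_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert energy_distance([0.0], [1.0]) == pytest.approx(np.sqrt(2))

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(loc=rng.uniform(-2, 2), size=rng.integers(2, 30))
            assert energy_distance(a, b) == pytest.approx(
                scipy.stats.energy_distance(a, b))

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        dists = [energy_distance(a, a + c) for c in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(x < y for x, y in zip(dists, dists[1:]))

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b, c = (rng.normal(loc=rng.uniform(-1, 1), size=8) for _ in range(3))
            assert energy_distance(a, b) == pytest.approx(energy_distance(b, a))
            assert energy_distance(a, c) <= (energy_distance(a, b)
                                             + energy_distance(b, c) + 1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            energy_distance([], [1.0])


class TestNormalization:
    def test_divide_by_global_maximum(self):
        df = pd.DataFrame({"descriptor": ["area", "area"],
                           "energy_distance": [2.0, 4.0]})
        out = normalize_energy_distances(df)
        assert list(out["normalized_energy_distance"]) == [0.5, 1.0]

    def test_all_zero_column_warns(self):
        df = pd.DataFrame({"descriptor": ["area"], "energy_distance": [0.0]})
        with pytest.warns(UserWarning):
            out = normalize_energy_distances(df)
        assert out["normalized_energy_distance"].iloc[0] == 0.0

    def test_order_preserved_within_descriptor(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"descriptor": ["perimeter"] * 10,
                           "energy_distance": rng.uniform(0.1, 5, 10)})
        out = normalize_energy_distances(df)
        assert (out["energy_distance"].rank() ==
                out["normalized_energy_distance"].rank()).all()


class TestEvaluateMethod:
    @staticmethod
    def masks(n=3, seed0=200):
        out = []
        for s in range(n):
            spec = synthetic.SynthSpec(height=96, width=96, phenotype="fragmented",
                                       n_objects=8, seed=seed0 + s)
            out.append(synthetic.generate_image(spec).mask)
        return out

    def test_identity_predictions_are_perfect(self):
        gt = self.masks()
        dice_df, morph_df = evaluate_method(gt, [m.copy() for m in gt])
        assert (dice_df["dice"] == 1.0).all()
        assert (morph_df["avg_fold_deviation"].dropna() == 1.0).all()
        assert (morph_df["energy_distance"] == 0.0).all()

    def test_row_layout_is_images_times_descriptors(self):
        gt = self.masks(12)
        _, morph_df = evaluate_method(gt, gt)
        assert len(morph_df) == 60  # 12 images x 5 descriptors

    def test_dilation_scores_strictly_worse(self):
        gt = self.masks()
        pred = [synthetic.perturb_mask(m.astype(np.uint8), "dilate", 1) for m in gt]
        dice_df, morph_df = evaluate_method(gt, pred)
        assert (dice_df["dice"] < 1.0).all()
        area = morph_df[morph_df["descriptor"] == "area"]
        assert (area["avg_fold_deviation"] > 1.0).all()

    def test_length_mismatch_rejected(self):
        gt = self.masks(2)
        with pytest.raises(ValueError):
            evaluate_method(gt, gt[:1])
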