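"""Tests for the Take-the-Best and fast-and-frugal-tree annotators."""

import numpy as np
import pytest

from dropal import TabularDataset
from dropal.dropout import MaskedInstance
from dropal.oracles import fft_label, fit_fft, fit_ttb, ttb_label


def make_dataset(X, y):
    return TabularDataset(np.asarray(X, float), np.asarray(y, int))


class TestFitTTB:
    def test_perfect_cue_ranks_first_with_accuracy_one(self, separable_2d):
        model = fit_ttb(separable_2d)
        assert model.cue_order[0] == 0
        assert model.accuracies[0] == 1.0
        assert model.directions[0] == 1

    def test_anticorrelated_cue_gets_flipped_direction(self):
        # attribute 0 is perfectly anti-correlated with the label
        X = [[8, 1], [7, 5], [6, 2], [5, 6], [3, 1], [2, 7], [1, 3], [0, 9]]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        model = fit_ttb(make_dataset(X, y))
        assert model.directions[0] == -1
        assert model.accuracies[0] == 1.0

    def test_constant_attribute_is_neutral_and_ranks_last(self):
        rng = np.random.default_rng(0)
        x0 = rng.uniform(-1, 1, 50)
        X = np.column_stack([x0, np.full(50, 3.0)])
        y = (x0 > np.median(x0)).astype(int)
        model = fit_ttb(make_dataset(X, y))
        assert model.accuracies[1] == 0.5
        assert model.directions[1] == 1
        assert model.cue_order[-1] == 1

    def test_accuracy_ranking_on_generated_sample(self, bias_dataset):
        model = fit_ttb(bias_dataset)
        # brute-force single-cue accuracy count as the independent check
        for j, (direction, acc) in enumerate(zip(model.directions, model.accuracies)):
            med = bias_dataset.medians[j]
            if direction == 1:
                pred = bias_dataset.X[:, j] > med
            else:
                pred = bias_dataset.X[:, j] < med
            assert acc == pytest.approx(np.mean(pred == bias_dataset.y))
            assert acc >= 0.5
        ranked = [model.accuracies[j] for j in model.cue_order]
        assert ranked == sorted(ranked, reverse=True)


class TestTTBLabel:
    @pytest.fixture
    def model(self, separable_2d):
        return fit_ttb(separable_2d)

    def test_best_visible_cue_decides(self, model, separable_2d):
        med = separable_2d.medians
        assert ttb_label(model, np.array([med[0] + 1.0, med[1]])) == 1
        assert ttb_label(model, np.array([med[0] - 1.0, med[1]])) == 0

    def test_masked_best_cue_falls_through_to_next(self, model, separable_2d):
        med = separable_2d.medians
        second = model.cue_order[1]
        query = np.array(med, dtype=float)
        query[second] = med[second] + 1.0 if model.directions[second] == 1 else med[second] - 1.0
        masked = MaskedInstance(query, np.array([False, True]))
        assert ttb_label(model, masked) == 1

    def test_all_visible_cues_at_median_yield_majority(self, model, separable_2d):
        assert ttb_label(model, np.array(separable_2d.medians)) == model.majority_class


class TestFitFFT:
    def test_depth_one_equals_best_median_split(self, bias_dataset):
        fft = fit_fft(bias_dataset, depth=1)
        ttb = fit_ttb(bias_dataset)
        assert fft.nodes[0].attribute == ttb.cue_order[0]
        # off-median instances: the two heuristics agree at depth 1
        for row in bias_dataset.X[:50]:
            if row[fft.nodes[0].attribute] != fft.nodes[0].threshold:
                assert fft_label(fft, row) == ttb_label(ttb, row)

    def test_depth_exceeding_attributes_rejected(self, separable_2d):
        with pytest.raises(ValueError):
            fit_fft(separable_2d, depth=3)

    def test_two_level_tree_matches_hand_rolled_rule(self, bias_dataset):
        fft = fit_fft(bias_dataset, depth=2)
        first, second = fft.nodes
        assert first.exit_side in ("above", "below")
        assert second.exit_side == "both"
        for row in bias_dataset.X[:50]:
            side = "above" if row[first.attribute] > first.threshold else "below"
            if side == first.exit_side:
                expected = first.exit_labels[side]
            else:
                side2 = "above" if row[second.attribute] > second.threshold else "below"
                expected = second.exit_labels[side2]
            assert fft_label(fft, row) == expected


class TestFFTLabel:
    def test_masked_node_is_skipped(self, diabetes_tree):
        # insulin below its split, bmi hidden, age above its split:
        # the decision comes from insulin and age alone
        query = MaskedInstance(
            np.array([80.0, 35.0, 50.0]), np.array([True, False, True])
        )
        assert fft_label(diabetes_tree, query) == 1
        young = MaskedInstance(
            np.array([80.0, 35.0, 30.0]), np.array([True, False, True])
        )
        assert fft_label(diabetes_tree, young) == 0

    def test_unmasked_traversal_is_plain_fft(self, diabetes_tree):
        assert fft_label(diabetes_tree, np.array([150.0, 20.0, 30.0])) == 1
        assert fft_label(diabetes_tree, np.array([80.0, 35.0, 30.0])) == 1

    def test_all_nodes_masked_yields_majority(self, diabetes_tree):
        query = MaskedInstance(
            np.array([150.0, 35.0, 50.0, 7.0]),
            np.array([False, False, False, True]),
        )
        assert fft_label(diabetes_tree, query) == diabetes_tree.majority_class


class TestMaskingProperties:
    def test_masking_unused_attribute_never_changes_label(self, bias_dataset):
        ttb = fit_ttb(bias_dataset)
        fft = fit_fft(bias_dataset, depth=3)
        best = ttb.cue_order[0]
        unused_fft = next(
            j for j in range(bias_dataset.d)
            if j not in {n.attribute for n in fft.nodes}
        )
        for row in bias_dataset.X[:100]:
            if row[best] == ttb.thresholds[best]:
                continue  # the best cue decides; any other attribute is unused
            for j in range(bias_dataset.d):
                if j == best:
                    continue
                visible = np.ones(bias_dataset.d, bool)
                visible[j] = False
                assert ttb_label(ttb, MaskedInstance(row, visible)) == ttb_label(ttb, row)
            visible = np.ones(bias_dataset.d, bool)
            visible[unused_fft] = False
            assert fft_label(fft, MaskedInstance(row, visible)) == fft_label(fft, row)

    def test_labels_are_deterministic(self, bias_dataset):
        ttb = fit_ttb(bias_dataset)
        row = bias_dataset.X[3]
        assert ttb_label(ttb, row) == ttb_label(ttb, row)

    def test_masking_best_cue_degrades_accuracy_on_average(self, bias_dataset):
        ttb = fit_ttb(bias_dataset)
        best = ttb.cue_order[0]
        visible = np.ones(bias_dataset.d, bool)
        visible[best] = False
        full = np.mean([
            ttb_label(ttb, row) == y
            for row, y in zip(bias_dataset.X, bias_dataset.y)
        ])
        masked = np.mean([
            ttb_label(ttb, MaskedInstance(row, visible)) == y
            for row, y in zip(bias_dataset.X, bias_dataset.y)
        ])
        assert masked <= full
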