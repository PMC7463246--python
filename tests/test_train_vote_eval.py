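import itertools

import numpy as np
import pytest

from mammofusion.errors import (
    DataError,
    ParameterError,
    TrainingError,
    UndefinedCurveError,
)
from mammofusion.fusion_models import FusionSpec, build_model
from mammofusion.patch_sampling import PatchSet
from mammofusion.preprocess import Roi
from mammofusion.train_vote_eval import (
    TrainConfig,
    classify_roi,
    compute_metrics,
    evaluate_model,
    majority_vote,
    roc_pr_curves,
    roi_tumor_score,
    round_half_up,
    train,
)


def _separable_patchset(n=200, seed=0):
    """Trivially separable patches: Normal = faint noise, Tumor = a bright
    centered square (both centralized)."""
    rng = np.random.default_rng(seed)
    pixels = np.zeros((n, 72, 72), np.float32)
    labels = np.zeros(n, int)
    for i in range(n):
        patch = rng.standard_normal((72, 72)).astype(np.float32) * 3
        if i % 2 == 1:
            patch[20:52, 20:52] += 60.0
            labels[i] = 1
        pixels[i] = patch - patch.mean()
    return PatchSet(pixels=pixels, labels=labels,
                    roi_refs=np.arange(n) % 10, offsets=np.zeros((n, 2), int))


def _biased_model(tumor: bool, seed=0):
    """Real tiny model rigged to always output one class."""
    model = build_model(FusionSpec(backbone="tiny_test"), seed=seed)
    model.params["head.out.weight"][:] = 0.0
    model.params["head.out.bias"][:] = [-20.0, 20.0] if tumor else [20.0, -20.0]
    return model


def _roi(seed=0):
    rng = np.random.default_rng(seed)
    return Roi(pixels=rng.integers(0, 256, (120, 120), dtype=np.uint8),
               label="Tumor", image_id="r", center_row=60, center_col=60,
               annotation_ref=0)


class TestTrainConfig:
    def test_invalid_epochs(self):
        with pytest.raises(ParameterError):
            TrainConfig(epochs=0)

    def test_invalid_lr(self):
        with pytest.raises(ParameterError):
            TrainConfig(learning_rate=0)


class TestTrain:
    @pytest.mark.parametrize("mode", ["fusion1", "fusion2"])
    def test_frozen_weights_bit_identical(self, mode):
        model = build_model(FusionSpec(backbone="tiny_test", mode=mode), seed=0)
        before = {k: model.params[k].copy() for k in model.frozen}
        ps = _separable_patchset(200)
        train(model, ps, None, TrainConfig(epochs=1, seed=0))
        for k, v in before.items():
            assert np.array_equal(model.params[k], v), k

    def test_loss_decreases_on_separable_data(self):
        model = build_model(FusionSpec(backbone="tiny_test"), seed=0)
        history = train(model, _separable_patchset(300), None,
                        TrainConfig(epochs=3, seed=0))
        losses = history["train_loss"]
        assert losses[0] > losses[1] > losses[2]

    def test_deterministic_given_seed(self):
        ps = _separable_patchset(120)
        final = []
        for _ in range(2):
            model = build_model(FusionSpec(backbone="tiny_test"), seed=1)
            train(model, ps, None, TrainConfig(epochs=2, seed=1))
            final.append({k: model.params[k].copy() for k in model.trainable})
        for k in final[0]:
            np.testing.assert_array_equal(final[0][k], final[1][k])

    def test_empty_training_set_errors(self):
        model = build_model(FusionSpec(backbone="tiny_test"), seed=0)
        empty = PatchSet(pixels=np.zeros((0, 72, 72), np.float32),
                         labels=np.zeros(0, int), roi_refs=np.zeros(0, int),
                         offsets=np.zeros((0, 2), int))
        with pytest.raises(DataError):
            train(model, empty, None, TrainConfig(epochs=1))

    def test_divergence_reported_with_epoch(self):
        model = build_model(FusionSpec(backbone="tiny_test"), seed=0)
        with pytest.raises(TrainingError, match="epoch 1"):
            train(model, _separable_patchset(100), None,
                  TrainConfig(epochs=1, learning_rate=1e12, seed=0))

    def test_history_and_early_stopping(self):
        model = build_model(FusionSpec(backbone="tiny_test"), seed=0)
        ps = _separable_patchset(200)
        val = _separable_patchset(80, seed=5)
        history = train(model, ps, val,
                        TrainConfig(epochs=4, seed=0, early_stopping_patience=2))
        assert len(history["val_loss"]) == len(history["train_loss"]) <= 4
        assert history["val_acc"][-1] > 0.9


class TestMajorityVote:
    def test_simple_majority(self):
        assert majority_vote(["Tumor"] * 13 + ["Normal"] * 12) == "Tumor"

    def test_unanimity(self):
        assert majority_vote(["Normal"] * 25) == "Normal"

    def test_tie_prefers_tumor(self):
        assert majority_vote(["Tumor", "Normal", "Tumor", "Normal"]) == "Tumor"

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            majority_vote([])

    def test_exhaustive_oracle_up_to_length_6(self):
        # independent count-and-argmax oracle over every binary list
        for length in range(1, 7):
            for combo in itertools.product(["Normal", "Tumor"], repeat=length):
                n_t = combo.count("Tumor")
                n_n = length - n_t
                if n_t > n_n:
                    expected = "Tumor"
                elif n_n > n_t:
                    expected = "Normal"
                else:
                    expected = "Tumor"  # tie rule
                assert majority_vote(list(combo)) == expected, combo


class TestClassifyRoi:
    def test_always_tumor_model(self):
        result = classify_roi(_biased_model(True), _roi(),
                              rng=np.random.default_rng(0))
        assert result.predicted_label == "Tumor"
        assert result.vote_fraction_tumor == 1.0
        assert result.n == 25  # default patch count

    def test_single_patch(self):
        result = classify_roi(_biased_model(False), _roi(), n=1,
                              rng=np.random.default_rng(0))
        assert result.n == 1
        assert result.predicted_label == "Normal"

    def test_deterministic(self):
        model = build_model(FusionSpec(backbone="tiny_test"), seed=3)
        a = classify_roi(model, _roi(), rng=np.random.default_rng(7))
        b = classify_roi(model, _roi(), rng=np.random.default_rng(7))
        assert a == b


class TestRoiTumorScore:
    def test_confident_tumor(self):
        s = roi_tumor_score(_biased_model(True), _roi(),
                            rng=np.random.default_rng(0))
        assert s == pytest.approx(1.0, abs=1e-6)

    def test_indifferent_model(self):
        model = _biased_model(True)
        model.params["head.out.bias"][:] = 0.0
        s = roi_tumor_score(model, _roi(), rng=np.random.default_rng(0))
        assert s == pytest.approx(0.5, abs=1e-6)

    def test_score_within_patch_prob_range(self):
        model = build_model(FusionSpec(backbone="tiny_test"), seed=1)
        rng = np.random.default_rng(2)
        from mammofusion.train_vote_eval import _roi_patch_probs
        probs = _roi_patch_probs(model, _roi(), 25, np.random.default_rng(2))
        s = roi_tumor_score(model, _roi(), rng=np.random.default_rng(2))
        assert probs[:, 1].min() - 1e-9 <= s <= probs[:, 1].max() + 1e-9


# back-solved confusion counts (tn, tp) on 41 Normal / 23 Tumor truth and
# the table rates they must reproduce at 4 decimals
TABLE_ROWS = [
    ((36, 21), {"Normal_recall": 0.8780, "Normal_precision": 0.9474,
                "Normal_f1": 0.9114, "Tumor_recall": 0.9130,
                "Tumor_precision": 0.8077, "Tumor_f1": 0.8571,
                "accuracy": 0.8906}),
    ((34, 22), {"Normal_recall": 0.8293, "Normal_precision": 0.9714,
                "Normal_f1": 0.8947, "Tumor_recall": 0.9565,
                "Tumor_precision": 0.7586, "Tumor_f1": 0.8462,
                "accuracy": 0.8750}),
    ((0, 23), {"Normal_recall": 0.0, "Normal_precision": 0.0,
               "Normal_f1": 0.0, "Tumor_recall": 1.0,
               "Tumor_precision": 0.3594, "Tumor_f1": 0.5287,
               "accuracy": 0.3594}),
    ((26, 23), {"Normal_recall": 0.6341, "Normal_precision": 1.0,
                "Normal_f1": 0.7761, "Tumor_recall": 1.0,
                "Tumor_precision": 0.6053, "Tumor_f1": 0.7541,
                "accuracy": 0.7656}),
    ((24, 23), {"Normal_recall": 0.5854, "Normal_precision": 1.0,
                "Normal_f1": 0.7385, "Tumor_recall": 1.0,
                "Tumor_precision": 0.5750, "Tumor_f1": 0.7302,
                "accuracy": 0.7344}),
]


def _labels_from_counts(tn, tp, n_normal=41, n_tumor=23):
    truth = ["Normal"] * n_normal + ["Tumor"] * n_tumor
    pred = (["Normal"] * tn + ["Tumor"] * (n_normal - tn)
            + ["Tumor"] * tp + ["Normal"] * (n_tumor - tp))
    return truth, pred


class TestComputeMetrics:
    @pytest.mark.parametrize("counts,expected", TABLE_ROWS)
    def test_reproduces_table_rows(self, counts, expected):
        truth, pred = _labels_from_counts(*counts)
        got = compute_metrics(truth, pred).rounded()
        for key, value in expected.items():
            assert got[key] == pytest.approx(value, abs=5e-5), key

    def test_all_correct(self):
        truth, pred = _labels_from_counts(41, 23)
        r = compute_metrics(truth, pred).rounded()
        assert all(v == 1.0 for v in r.values())

    def test_confusion_counts(self):
        truth, pred = _labels_from_counts(36, 21)
        rep = compute_metrics(truth, pred)
        assert (rep.tn, rep.fp, rep.fn, rep.tp) == (36, 5, 2, 21)
        assert rep.tn + rep.fp + rep.fn + rep.tp == 64

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            compute_metrics(["Normal"], ["Normal", "Tumor"])

    def test_never_predicted_class_defined_as_zero(self):
        rep = compute_metrics(["Normal", "Tumor"], ["Tumor", "Tumor"])
        assert rep.per_class["Normal"]["precision"] == 0.0
        assert rep.per_class["Normal"]["f1"] == 0.0

    def test_round_half_up(self):
        assert round_half_up(0.890625) == 0.8906
        assert round_half_up(0.35935) == 0.3594
        assert round_half_up(0.12345) == 0.1235


class TestRocPrCurves:
    def test_perfect_separation(self):
        out = roc_pr_curves([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert out["roc"]["auc"] == pytest.approx(1.0)

    def test_identical_scores_chance(self):
        out = roc_pr_curves([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert out["roc"]["auc"] == pytest.approx(0.5)

    def test_uniform_scores_monte_carlo(self):
        rng = np.random.default_rng(123)
        truth = rng.integers(0, 2, 2000)
        scores = rng.random(2000)
        out = roc_pr_curves(truth, scores)
        assert out["roc"]["auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_errors(self):
        with pytest.raises(UndefinedCurveError):
            roc_pr_curves([1, 1, 1], [0.1, 0.5, 0.9])

    def test_curves_monotone(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 50)
        scores = rng.random(50)
        out = roc_pr_curves(truth, scores)
        assert (np.diff(out["roc"]["fpr"]) >= 0).all()
        assert (np.diff(out["roc"]["tpr"]) >= 0).all()


class TestEvaluateModel:
    def test_degenerate_tumor_predictor_matches_table(self):
        rois = ([Roi(pixels=np.full((120, 120), 50, np.uint8), label="Normal",
                     image_id=f"n{i}", center_row=60, center_col=60)
                 for i in range(41)]
                + [Roi(pixels=np.full((120, 120), 50, np.uint8), label="Tumor",
                       image_id=f"t{i}", center_row=60, center_col=60,
                       annotation_ref=i) for i in range(23)])
        report, votes = evaluate_model(_biased_model(True), rois, seed=0)
        r = report.rounded()
        assert r["accuracy"] == pytest.approx(0.3594)
        assert r["Normal_recall"] == 0.0
        assert r["Tumor_recall"] == 1.0
        assert all(v.predicted_label == "Tumor" for v in votes)

    def test_vote_fraction_consistency(self):
        rois = [_roi(seed=s) for s in range(3)]
        _, votes = evaluate_model(_biased_model(False), rois, seed=0)
        for v in votes:
            assert (v.predicted_label == "Tumor") == (v.vote_fraction_tumor > 0.5)
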