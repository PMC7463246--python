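"""Head training, majority-vote ROI classification, and evaluation.

Training touches only the trainable parameters of a
:class:`~mammofusion.fusion_models.ModelHandle`; frozen backbone weights
are bit-identical before and after.  ROI classification samples ``n``
patches (default 25), predicts each, and takes the modal label.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from . import _nn
from .errors import DataError, ParameterError, TrainingError, UndefinedCurveError
from .fusion_models import ModelHandle
from .patch_sampling import PatchSet, sample_patches
from .preprocess import Roi

logger = logging.getLogger(__name__)

LABELS = ("Normal", "Tumor")
VOTE_PATCHES = 25  # patches voted per ROI


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0
    early_stopping_patience: int = 5
    class_weighting: bool = False
    augment: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if self.loss != "cross_entropy":
            raise ParameterError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ParameterError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class VotingResult:
    roi_ref: int
    predicted_label: str
    vote_fraction_tumor: float
    n: int


@dataclass
class EvalReport:
    tn: int
    fp: int
    fn: int
    tp: int
    per_class: Dict[str, Dict[str, float]]  # label -> recall/precision/f1
    accuracy: float
    roc: Optional[dict] = None  # fpr, tpr, thresholds, auc
    pr: Optional[dict] = None  # precision, recall, thresholds, auc

    def rounded(self, places: int = 4) -> dict:
        """Half-up rounded scalar metrics, as printed in result tables."""
        out = {"accuracy": round_half_up(self.accuracy, places)}
        for label, metrics in self.per_class.items():
            for k, v in metrics.items():
                out[f"{label}_{k}"] = round_half_up(v, places)
        if self.roc is not None:
            out["roc_auc"] = round_half_up(self.roc["auc"], places)
        if self.pr is not None:
            out["pr_auc"] = round_half_up(self.pr["auc"], places)
        return out

    def as_dict(self) -> dict:
        d = {"confusion": {"tn": self.tn, "fp": self.fp,
                           "fn": self.fn, "tp": self.tp},
             "accuracy": self.accuracy,
             "per_class": self.per_class}
        if self.roc is not None:
            d["roc_auc"] = self.roc["auc"]
        if self.pr is not None:
            d["pr_auc"] = self.pr["auc"]
        return d


def round_half_up(value: float, places: int = 4) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# training


def _cache_features(model: ModelHandle, pixels: np.ndarray,
                    chunk: int = 256) -> List[np.ndarray]:
    """Frozen-backbone block maps for a whole patch array, float32."""
    outs: Optional[List[List[np.ndarray]]] = None
    for start in range(0, len(pixels), chunk):
        feats = model.backbone_forward(pixels[start : start + chunk])
        if outs is None:
            outs = [[] for _ in feats]
        for acc, f in zip(outs, feats):
            acc.append(f.astype(np.float32))
    assert outs is not None
    return [np.concatenate(acc) for acc in outs]


def _channel_stats(chunks) -> tuple:
    """Exact per-channel mean/variance over an iterable of (N,C,...) blocks."""
    n = 0
    s = sq = None
    for block in chunks:
        axes = tuple(i for i in range(block.ndim) if i != 1)
        b64 = block.astype(np.float64)
        bs = b64.sum(axis=axes)
        bsq = (b64 * b64).sum(axis=axes)
        n += int(np.prod([block.shape[i] for i in axes]))
        s = bs if s is None else s + bs
        sq = bsq if sq is None else sq + bsq
    mean = s / n
    var = np.maximum(sq / n - mean * mean, 0.0)
    return mean, var


def calibrate_bn(model: ModelHandle, feats: List[np.ndarray],
                 chunk: int = 1024,
                 branch_stats: Optional[list] = None) -> list:
    """Set BN running buffers to exact statistics over the given patch
    features (inference-mode normalization then matches the data the head
    was trained on, regardless of how few optimizer steps ran).

    Branch BN inputs are the frozen backbone maps, so their statistics are
    computed once and can be re-used via ``branch_stats``.  Returns the
    branch statistics for that re-use.
    """
    n = len(feats[0])
    if model.spec.mode == "fusion2":
        if branch_stats is None:
            branch_stats = [
                _channel_stats(f[i : i + chunk] for i in range(0, n, chunk))
                for f in feats
            ]
        for b, (mean, var) in zip(model.spec.branches, branch_stats):
            model.buffers[f"branch{b}.bn.running_mean"][:] = mean
            model.buffers[f"branch{b}.bn.running_var"][:] = var
    mean, var = _channel_stats(
        model.fusion_vector([f[i : i + chunk] for f in feats])
        for i in range(0, n, chunk))
    model.buffers["head.bn.running_mean"][:] = mean
    model.buffers["head.bn.running_var"][:] = var
    return branch_stats if branch_stats is not None else []


def _evaluate_patches(model: ModelHandle, feats: List[np.ndarray],
                      labels: np.ndarray, batch_size: int,
                      sample_weights: Optional[np.ndarray]) -> tuple:
    losses, correct, total = [], 0, 0
    for start in range(0, len(labels), batch_size):
        sl = slice(start, start + batch_size)
        probs, _ = model.head_forward([f[sl] for f in feats], training=False)
        w = None if sample_weights is None else sample_weights[sl]
        loss, _ = _nn.cross_entropy(probs, labels[sl], w)
        losses.append(loss * len(labels[sl]))
        correct += int((probs.argmax(axis=1) == labels[sl]).sum())
        total += len(labels[sl])
    return float(np.sum(losses) / total), correct / total


def train(model: ModelHandle, train_patches: PatchSet,
          val_patches: Optional[PatchSet], config: TrainConfig) -> dict:
    """Fit the trainable head; returns the history dict.  The model is
    updated in place and left at its best-validation-loss state."""
    if len(train_patches) == 0:
        raise DataError("empty training set")
    rng = np.random.default_rng(config.seed)
    y = train_patches.labels
    weights = None
    if config.class_weighting:
        freq = np.bincount(y, minlength=model.spec.n_classes).astype(float)
        inv = np.where(freq > 0, len(y) / (model.spec.n_classes * np.maximum(freq, 1)), 0.0)
        weights = inv[y]

    train_feats = _cache_features(model, train_patches.pixels)
    val_feats = val_labels = None
    if val_patches is not None and len(val_patches) > 0:
        val_feats = _cache_features(model, val_patches.pixels)
        val_labels = val_patches.labels
    # branch BN inputs are frozen features: their statistics never change
    branch_stats = calibrate_bn(model, train_feats) or None

    opt = _nn.Adam(lr=config.learning_rate)
    trainable = sorted(model.trainable)
    history: Dict[str, list] = {k: [] for k in
                                ("train_loss", "train_acc", "val_loss", "val_acc")}
    best_val = np.inf
    best_state: Optional[dict] = None
    patience_left = config.early_stopping_patience

    n = len(y)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            feats = [f[idx] for f in train_feats]
            probs, cache = model.head_forward(feats, training=True)
            w = None if weights is None else weights[idx]
            loss, dlogits = _nn.cross_entropy(probs, y[idx], w)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            grads = model.head_backward(dlogits, cache)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            epoch_correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(epoch_correct / n)
        calibrate_bn(model, train_feats, branch_stats=branch_stats)

        if val_feats is not None:
            val_loss, val_acc = _evaluate_patches(
                model, val_feats, val_labels, config.batch_size,
                None)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            logger.info("epoch %d: train loss %.4f acc %.4f | val loss %.4f acc %.4f",
                        epoch, history["train_loss"][-1],
                        history["train_acc"][-1], val_loss, val_acc)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = {
                    "params": {k: model.params[k].copy() for k in trainable},
                    "buffers": {k: v.copy() for k, v in model.buffers.items()},
                }
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stopping at epoch %d", epoch)
                    break
        else:
            logger.info("epoch %d: train loss %.4f acc %.4f", epoch,
                        history["train_loss"][-1], history["train_acc"][-1])

    if best_state is not None:
        model.params.update(best_state["params"])
        model.buffers.update(best_state["buffers"])
    return history


# --------------------------------------------------------------------------
# voting and scoring


def majority_vote(labels: Sequence[str], tie_rule: str = "prefer_tumor") -> str:
    """Modal label; exact binary ties resolved by the tie rule."""
    if len(labels) == 0:
        raise ParameterError("cannot vote over an empty label list")
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    top = counts.max()
    winners = sorted(str(v) for v, c in zip(values, counts) if c == top)
    if len(winners) == 1:
        return winners[0]
    if tie_rule == "prefer_tumor" and "Tumor" in winners:
        return "Tumor"
    return winners[0]


def _roi_patch_probs(model: ModelHandle, roi: Roi, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    patches = sample_patches(roi, n, size=model.input_size, rng=rng,
                             centralized=True)
    batch = np.stack([p.pixels for p in patches])
    probs, _ = model.forward(batch, training=False)
    return probs


def classify_roi(model: ModelHandle, roi: Roi, n: int = VOTE_PATCHES,
                 rng: Optional[np.random.Generator] = None,
                 roi_ref: int = -1,
                 tie_rule: str = "prefer_tumor") -> VotingResult:
    """Majority vote over n freshly sampled patches of the ROI."""
    rng = rng or np.random.default_rng()
    probs = _roi_patch_probs(model, roi, n, rng)
    patch_labels = [LABELS[int(i)] for i in probs.argmax(axis=1)]
    fraction = patch_labels.count("Tumor") / n
    return VotingResult(
        roi_ref=roi_ref,
        predicted_label=majority_vote(patch_labels, tie_rule),
        vote_fraction_tumor=fraction,
        n=n,
    )


def roi_tumor_score(model: ModelHandle, roi: Roi, n: int = VOTE_PATCHES,
                    rng: Optional[np.random.Generator] = None) -> float:
    """Mean Tumor-class softmax probability over n sampled patches."""
    rng = rng or np.random.default_rng()
    return float(_roi_patch_probs(model, roi, n, rng)[:, 1].mean())


# --------------------------------------------------------------------------
# metrics


def _as_binary(labels: Sequence) -> np.ndarray:
    out = []
    for v in labels:
        if isinstance(v, str):
            if v not in LABELS:
                raise DataError(f"unknown label {v!r}")
            out.append(LABELS.index(v))
        else:
            iv = int(v)
            if iv not in (0, 1):
                raise DataError(f"labels must be binary, got {v!r}")
            out.append(iv)
    return np.asarray(out)


def compute_metrics(true_labels: Sequence, predicted_labels: Sequence) -> EvalReport:
    """Confusion counts (Tumor positive) and per-class recall/precision/F1."""
    if len(true_labels) != len(predicted_labels):
        raise DataError("true/predicted label lists differ in length")
    if len(true_labels) == 0:
        raise DataError("empty label lists")
    t = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())

    per_class = {}
    for label, (tp_c, fp_c, fn_c) in (("Normal", (tn, fn, fp)),
                                      ("Tumor", (tp, fp, fn))):
        recall = tp_c / (tp_c + fn_c) if tp_c + fn_c > 0 else 0.0
        precision = tp_c / (tp_c + fp_c) if tp_c + fp_c > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        per_class[label] = {"recall": recall, "precision": precision, "f1": f1}
    return EvalReport(tn=tn, fp=fp, fn=fn, tp=tp, per_class=per_class,
                      accuracy=(tn + tp) / len(t))


def roc_pr_curves(true_labels: Sequence, scores: Sequence[float]) -> dict:
    """Threshold-sweep ROC and PR curves with trapezoidal AUCs."""
    t = _as_binary(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise DataError("labels and scores differ in length")
    if len(np.unique(t)) < 2:
        raise UndefinedCurveError("ROC/PR undefined for single-class truth")
    fpr, tpr, roc_thr = roc_curve(t, s)
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision, recall, pr_thr = precision_recall_curve(t, s)
    order = np.argsort(recall)
    pr_auc = float(np.trapezoid(precision[order], recall[order]))
    return {
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                "thresholds": roc_thr.tolist(), "auc": roc_auc},
        "pr": {"precision": precision.tolist(), "recall": recall.tolist(),
               "thresholds": pr_thr.tolist(), "auc": pr_auc},
    }


def evaluate_model(model: ModelHandle, rois: Sequence[Roi],
                   roi_refs: Optional[Sequence[int]] = None,
                   n: int = VOTE_PATCHES, seed: int = 0,
                   score: str = "mean_prob") -> tuple:
    """Vote-classify every ROI and assemble the full report.

    Returns (EvalReport, list[VotingResult]).  ``score`` selects the
    ROC/PR ranking statistic: mean Tumor probability or vote fraction.
    """
    if score not in ("mean_prob", "vote_fraction"):
        raise ParameterError(f"unknown score {score!r}")
    rng = np.random.default_rng(seed)
    results, scores, truths, preds = [], [], [], []
    refs = roi_refs if roi_refs is not None else range(len(rois))
    for ref, roi in zip(refs, rois):
        probs = _roi_patch_probs(model, roi, n, rng)
        patch_labels = [LABELS[int(i)] for i in probs.argmax(axis=1)]
        vote = VotingResult(
            roi_ref=int(ref),
            predicted_label=majority_vote(patch_labels),
            vote_fraction_tumor=patch_labels.count("Tumor") / n,
            n=n,
        )
        results.append(vote)
        truths.append(roi.label)
        preds.append(vote.predicted_label)
        scores.append(float(probs[:, 1].mean()) if score == "mean_prob"
                      else vote.vote_fraction_tumor)
    report = compute_metrics(truths, preds)
    try:
        curves = roc_pr_curves(truths, scores)
        report.roc = curves["roc"]
        report.pr = curves["pr"]
    except UndefinedCurveError:
        pass
    return report, results
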