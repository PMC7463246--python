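"""Multi-scale fusion classifiers over a frozen convolutional backbone.

Two head variants share the same trunk wiring:

* ``fusion1``: global-average-pool each selected backbone block, then
  concatenate the pooled vectors.
* ``fusion2``: per selected block, BN -> 2x2 average pool -> pointwise
  (1x1) convolution with ReLU -> global average pool, then concatenate.

The concatenated vector feeds BN -> FC1 (ReLU) -> FC2 (ReLU) -> softmax
output.  Backbone convolutions are always frozen; everything after the
block taps is trainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import _nn
from .errors import DependencyError, SpecError

# per-block channel widths and conv-layer counts
BACKBONES = {
    "vgg16": {"widths": (64, 128, 256, 512, 512), "convs": (2, 2, 3, 3, 3)},
    "vgg19": {"widths": (64, 128, 256, 512, 512), "convs": (2, 2, 4, 4, 4)},
    "tiny_test": {"widths": (8, 16, 32, 32, 32), "convs": (1, 1, 1, 1, 1)},
}


@dataclass(frozen=True)
class FusionSpec:
    backbone: str = "vgg16"
    branches: Tuple[int, ...] = (1, 2, 3, 4, 5)
    mode: str = "fusion1"
    bottleneck_channels: int = 64
    fc1_width: int = 256
    fc2_width: int = 128
    n_classes: int = 2
    pretrained: bool = False

    def validate(self) -> None:
        if self.backbone not in BACKBONES:
            raise SpecError(f"unknown backbone {self.backbone!r}")
        if self.mode not in ("fusion1", "fusion2"):
            raise SpecError(f"unknown fusion mode {self.mode!r}")
        if not self.branches:
            raise SpecError("branch subset must be non-empty")
        if any(b not in (1, 2, 3, 4, 5) for b in self.branches):
            raise SpecError(f"branches must lie in 1..5, got {self.branches}")
        if len(set(self.branches)) != len(self.branches):
            raise SpecError(f"duplicate branches in {self.branches}")
        if self.mode == "fusion2" and self.bottleneck_channels < 1:
            raise SpecError("bottleneck_channels must be >= 1 for fusion2")
        if self.n_classes < 2:
            raise SpecError("n_classes must be >= 2")
        if min(self.fc1_width, self.fc2_width) < 1:
            raise SpecError("FC widths must be >= 1")

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone,
            "branches": list(self.branches),
            "mode": self.mode,
            "bottleneck_channels": self.bottleneck_channels,
            "fc1_width": self.fc1_width,
            "fc2_width": self.fc2_width,
            "n_classes": self.n_classes,
            "pretrained": self.pretrained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionSpec":
        d = dict(d)
        d["branches"] = tuple(d["branches"])
        return cls(**d)


def fused_dimension(spec: FusionSpec) -> int:
    """Width of the concatenated feature vector entering the head BN."""
    spec.validate()
    widths = BACKBONES[spec.backbone]["widths"]
    if spec.mode == "fusion1":
        return sum(widths[b - 1] for b in spec.branches)
    return len(spec.branches) * spec.bottleneck_channels


@dataclass
class ModelHandle:
    """Assembled network: parameter arrays, BN buffers, and the partition
    of parameter names into frozen and trainable sets."""

    spec: FusionSpec
    params: Dict[str, np.ndarray]
    buffers: Dict[str, np.ndarray]
    frozen: frozenset
    input_size: int = 72

    @property
    def trainable(self) -> frozenset:
        return frozenset(self.params) - self.frozen

    # ----- forward passes -------------------------------------------------

    def backbone_forward(self, x: np.ndarray) -> list:
        """Run the frozen trunk; returns the selected post-pool block maps."""
        x = self._as_batch(x)
        convs = BACKBONES[self.spec.backbone]["convs"]
        feats = []
        h = x
        for bi, n_convs in enumerate(convs, start=1):
            for ci in range(n_convs):
                w = self.params[f"backbone.block{bi}.conv{ci}.weight"]
                b = self.params[f"backbone.block{bi}.conv{ci}.bias"]
                h = _nn.relu(_nn.conv2d_3x3(h, w, b))
            h = _nn.maxpool2(h)
            feats.append(h)
        return [feats[b - 1] for b in self.spec.branches]

    def head_forward(self, feats: list, training: bool = False):
        """Fusion head over the block maps; returns (probs, cache)."""
        p, bufs, spec = self.params, self.buffers, self.spec
        cache: dict = {"feats": feats, "training": training}
        if spec.mode == "fusion1":
            gaps = [_nn.gap(f) for f in feats]
        else:
            gaps = []
            branch_caches = []
            for f, b in zip(feats, spec.branches):
                pre = f"branch{b}"
                u, bn_cache = _nn.batchnorm_forward(
                    f, p[f"{pre}.bn.gamma"], p[f"{pre}.bn.beta"],
                    bufs[f"{pre}.bn.running_mean"],
                    bufs[f"{pre}.bn.running_var"], training)
                v = _nn.avgpool2(u)
                s_pre = _nn.conv1x1(v, p[f"{pre}.conv1x1.weight"],
                                    p[f"{pre}.conv1x1.bias"])
                s = _nn.relu(s_pre)
                gaps.append(_nn.gap(s))
                branch_caches.append((bn_cache, u.shape, v, s_pre, s.shape))
            cache["branches"] = branch_caches
        z = np.concatenate(gaps, axis=1)
        cache["gap_widths"] = [g.shape[1] for g in gaps]
        zbn, cache["head_bn"] = _nn.batchnorm_forward(
            z, p["head.bn.gamma"], p["head.bn.beta"],
            bufs["head.bn.running_mean"], bufs["head.bn.running_var"],
            training)
        h1_pre = zbn @ p["head.fc1.weight"].T + p["head.fc1.bias"]
        h1 = _nn.relu(h1_pre)
        h2_pre = h1 @ p["head.fc2.weight"].T + p["head.fc2.bias"]
        h2 = _nn.relu(h2_pre)
        logits = h2 @ p["head.out.weight"].T + p["head.out.bias"]
        probs = _nn.softmax(logits)
        cache.update(zbn=zbn, h1_pre=h1_pre, h1=h1, h2_pre=h2_pre, h2=h2)
        return probs, cache

    def fusion_vector(self, feats: list) -> np.ndarray:
        """Concatenated pre-head-BN fusion vector, inference mode."""
        p, bufs, spec = self.params, self.buffers, self.spec
        if spec.mode == "fusion1":
            gaps = [_nn.gap(f) for f in feats]
        else:
            gaps = []
            for f, b in zip(feats, spec.branches):
                pre = f"branch{b}"
                u, _ = _nn.batchnorm_forward(
                    f, p[f"{pre}.bn.gamma"], p[f"{pre}.bn.beta"],
                    bufs[f"{pre}.bn.running_mean"],
                    bufs[f"{pre}.bn.running_var"], training=False)
                s = _nn.relu(_nn.conv1x1(_nn.avgpool2(u),
                                         p[f"{pre}.conv1x1.weight"],
                                         p[f"{pre}.conv1x1.bias"]))
                gaps.append(_nn.gap(s))
        return np.concatenate(gaps, axis=1)

    def head_backward(self, dlogits: np.ndarray, cache: dict) -> Dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every trainable parameter."""
        p, spec = self.params, self.spec
        grads: Dict[str, np.ndarray] = {}
        grads["head.out.weight"] = dlogits.T @ cache["h2"]
        grads["head.out.bias"] = dlogits.sum(axis=0)
        dh2 = (dlogits @ p["head.out.weight"]) * (cache["h2_pre"] > 0)
        grads["head.fc2.weight"] = dh2.T @ cache["h1"]
        grads["head.fc2.bias"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["head.fc2.weight"]) * (cache["h1_pre"] > 0)
        grads["head.fc1.weight"] = dh1.T @ cache["zbn"]
        grads["head.fc1.bias"] = dh1.sum(axis=0)
        need_dz = spec.mode == "fusion2"
        dz, dg, db = _nn.batchnorm_backward(
            dh1 @ p["head.fc1.weight"], cache["head_bn"],
            p["head.bn.gamma"], need_dx=need_dz)
        grads["head.bn.gamma"] = dg
        grads["head.bn.beta"] = db
        if need_dz:
            splits = np.cumsum(cache["gap_widths"])[:-1]
            dgaps = np.split(dz, splits, axis=1)
            for dgap, b, (bn_cache, u_shape, v, s_pre, s_shape) in zip(
                    dgaps, spec.branches, cache["branches"]):
                pre = f"branch{b}"
                ds = _nn.gap_backward(dgap, s_shape) * (s_pre > 0)
                dv, dw, dbias = _nn.conv1x1_backward(
                    ds, v, p[f"{pre}.conv1x1.weight"])
                grads[f"{pre}.conv1x1.weight"] = dw
                grads[f"{pre}.conv1x1.bias"] = dbias
                du = _nn.avgpool2_backward(dv, u_shape)
                _, dgam, dbet = _nn.batchnorm_backward(
                    du, bn_cache, p[f"{pre}.bn.gamma"], need_dx=False)
                grads[f"{pre}.bn.gamma"] = dgam
                grads[f"{pre}.bn.beta"] = dbet
        return grads

    def forward(self, x: np.ndarray, training: bool = False):
        return self.head_forward(self.backbone_forward(x), training)

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:  # (N, H, W) grayscale -> replicate channels
            x = np.repeat(x[:, None], 3, axis=1)
        if x.ndim != 4 or x.shape[1] != 3:
            raise SpecError(f"expected (N,3,H,W) or (N,H,W) batch, got {x.shape}")
        if x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise SpecError(
                f"expected {self.input_size}x{self.input_size} patches, "
                f"got {x.shape[2]}x{x.shape[3]}")
        return x


def build_model(spec: FusionSpec, seed: int = 0,
                backbone_weights: Optional[dict] = None) -> ModelHandle:
    """Assemble the network; backbone convs frozen, head randomly
    initialized with uniform fan-in scaling under ``seed``."""
    spec.validate()
    if spec.pretrained and backbone_weights is None:
        raise DependencyError(
            f"pretrained weights for {spec.backbone!r} are not bundled and no "
            "backbone_weights mapping was supplied; build with "
            "pretrained=False or pass the weights explicitly")
    rng = np.random.default_rng(seed)
    arch = BACKBONES[spec.backbone]
    params: Dict[str, np.ndarray] = {}
    buffers: Dict[str, np.ndarray] = {}
    frozen = set()

    in_ch = 3
    for bi, (width, n_convs) in enumerate(zip(arch["widths"], arch["convs"]),
                                          start=1):
        for ci in range(n_convs):
            wname = f"backbone.block{bi}.conv{ci}.weight"
            bname = f"backbone.block{bi}.conv{ci}.bias"
            if backbone_weights is not None:
                params[wname] = np.array(backbone_weights[wname], np.float32)
                params[bname] = np.array(backbone_weights[bname], np.float32)
            else:
                fan_in = in_ch * 9
                params[wname] = _nn.uniform_fan_in(rng, (width, in_ch, 3, 3), fan_in)
                params[bname] = _nn.uniform_fan_in(rng, (width,), fan_in)
            frozen.update((wname, bname))
            in_ch = width

    widths = arch["widths"]
    if spec.mode == "fusion2":
        for b in spec.branches:
            c = widths[b - 1]
            k = spec.bottleneck_channels
            pre = f"branch{b}"
            params[f"{pre}.bn.gamma"] = np.ones(c, np.float32)
            params[f"{pre}.bn.beta"] = np.zeros(c, np.float32)
            buffers[f"{pre}.bn.running_mean"] = np.zeros(c, np.float32)
            buffers[f"{pre}.bn.running_var"] = np.ones(c, np.float32)
            params[f"{pre}.conv1x1.weight"] = _nn.uniform_fan_in(rng, (k, c), c)
            params[f"{pre}.conv1x1.bias"] = _nn.uniform_fan_in(rng, (k,), c)

    d = fused_dimension(spec)
    params["head.bn.gamma"] = np.ones(d, np.float32)
    params["head.bn.beta"] = np.zeros(d, np.float32)
    buffers["head.bn.running_mean"] = np.zeros(d, np.float32)
    buffers["head.bn.running_var"] = np.ones(d, np.float32)
    for name, (n_out, n_in) in (
        ("fc1", (spec.fc1_width, d)),
        ("fc2", (spec.fc2_width, spec.fc1_width)),
        ("out", (spec.n_classes, spec.fc2_width)),
    ):
        params[f"head.{name}.weight"] = _nn.uniform_fan_in(rng, (n_out, n_in), n_in)
        params[f"head.{name}.bias"] = _nn.uniform_fan_in(rng, (n_out,), n_in)

    return ModelHandle(spec=spec, params=params, buffers=buffers,
                       frozen=frozenset(frozen))


def trainable_parameter_names(model: ModelHandle) -> frozenset:
    """Names of parameters updated during training (everything non-frozen)."""
    return model.trainable


def predict_patch_probs(model: ModelHandle, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities for a batch of patches."""
    batch = np.asarray(batch)
    if batch.shape[0] == 0:
        return np.zeros((0, model.spec.n_classes))
    probs, _ = model.forward(batch, training=False)
    return probs


def save_checkpoint(model: ModelHandle, path) -> None:
    """Write <path>.json (spec, self-describing) and <path>.npz (arrays)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".json").write_text(
        json.dumps({"spec": model.spec.to_dict(),
                    "frozen": sorted(model.frozen),
                    "input_size": model.input_size}, indent=2))
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    arrays.update({f"buffer::{k}": v for k, v in model.buffers.items()})
    np.savez(path.with_suffix(".npz"), **arrays)


def load_checkpoint(path) -> ModelHandle:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    params, buffers = {}, {}
    for key in data.files:
        kind, name = key.split("::", 1)
        (params if kind == "param" else buffers)[name] = data[key]
    return ModelHandle(spec=FusionSpec.from_dict(meta["spec"]), params=params,
                       buffers=buffers, frozen=frozenset(meta["frozen"]),
                       input_size=meta.get("input_size", 72))
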