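"""ROI splitting and random patch sampling.

ROIs are split 60/20/20 stratified by label; patches are 72x72 crops
drawn uniformly (with replacement) from the offset lattice, centralized
by per-patch mean subtraction, and optionally augmented with flips and
quarter-turns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import DataError, ParameterError
from .preprocess import Roi

PATCH_SIZE = 72
SPLITS = ("train", "val", "test")
DEFAULT_COUNTS = {"Normal": 500, "Tumor": 2000}
AUGMENT_OPS = ("hflip", "vflip", "rot90", "none")


@dataclass(frozen=True)
class Patch:
    """A single (possibly centralized) patch with ROI provenance."""

    pixels: np.ndarray  # (size, size) float32
    label: str
    roi_ref: int
    offset: tuple[int, int]  # (top, left) within the ROI


@dataclass(frozen=True)
class SplitAssignment:
    """Mapping roi_ref -> split name; a disjoint, exhaustive partition."""

    assignment: Dict[int, str]

    def refs(self, split: str) -> list[int]:
        return [r for r, s in self.assignment.items() if s == split]

    def __getitem__(self, roi_ref: int) -> str:
        return self.assignment[roi_ref]


@dataclass
class PatchSet:
    """Columnar patch container for one split."""

    pixels: np.ndarray  # (N, size, size) float32, centralized
    labels: np.ndarray  # (N,) int, 0=Normal 1=Tumor
    roi_refs: np.ndarray  # (N,) int
    offsets: np.ndarray  # (N, 2) int

    def __len__(self) -> int:
        return int(self.pixels.shape[0])


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items over the fractions."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    remainder = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest frac part first
    for k in range(remainder):
        base[order[k]] += 1
    return base


def split_rois(
    rois: Sequence[Roi],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified-by-label train/val/test split at ROI level."""
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ParameterError(f"fractions must be non-negative and sum to 1: {fractions}")
    by_label: Dict[str, list[int]] = {}
    for i, roi in enumerate(rois):
        by_label.setdefault(roi.label, []).append(i)
    missing = {"Normal", "Tumor"} - set(by_label)
    if missing:
        raise DataError(f"at least one ROI per class is required; "
                        f"missing {sorted(missing)}")
    rng = np.random.default_rng(seed)
    assignment: Dict[int, str] = {}
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        counts = _allocate(len(idx), fractions)
        start = 0
        for split, cnt in zip(SPLITS, counts):
            for r in idx[start : start + cnt]:
                assignment[int(r)] = split
            start += cnt
    return SplitAssignment(assignment=assignment)


def sample_patches(
    roi: Roi,
    n: int,
    size: int = PATCH_SIZE,
    rng: Optional[np.random.Generator] = None,
    roi_ref: int = -1,
    centralized: bool = True,
) -> List[Patch]:
    """Draw n patches at offsets uniform on {0..side-size}^2 with replacement."""
    side = roi.pixels.shape[0]
    if size > side:
        raise ParameterError(f"patch size {size} exceeds ROI side {side}")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = rng or np.random.default_rng()
    max_off = side - size
    tops = rng.integers(0, max_off + 1, size=n)
    lefts = rng.integers(0, max_off + 1, size=n)
    patches = []
    for t, l in zip(tops, lefts):
        px = roi.pixels[t : t + size, l : l + size].astype(np.float32)
        p = Patch(pixels=px, label=roi.label, roi_ref=roi_ref, offset=(int(t), int(l)))
        patches.append(centralize(p) if centralized else p)
    return patches


def centralize(patch: Patch) -> Patch:
    """Subtract the patch's own mean intensity."""
    px = patch.pixels.astype(np.float32)
    return Patch(
        pixels=px - px.mean(dtype=np.float64).astype(np.float32),
        label=patch.label,
        roi_ref=patch.roi_ref,
        offset=patch.offset,
    )


def _apply_op(px: np.ndarray, op: str) -> np.ndarray:
    if op == "hflip":
        return px[:, ::-1]
    if op == "vflip":
        return px[::-1, :]
    if op == "rot90":
        return np.rot90(px)
    if op == "none":
        return px
    raise ParameterError(f"unknown augmentation op {op!r}")


def augment(
    patch: Patch,
    rng: np.random.Generator,
    ops: Sequence[str] = ("hflip", "vflip", "rot90"),
    prob: float = 0.5,
) -> Patch:
    """Apply each isometry with probability ``prob``, in the given order."""
    for op in ops:
        if op not in AUGMENT_OPS:
            raise ParameterError(f"unknown augmentation op {op!r}")
    px = patch.pixels
    for op in ops:
        if op == "none":
            continue
        if rng.random() < prob:
            px = _apply_op(px, op)
    return Patch(pixels=np.ascontiguousarray(px), label=patch.label,
                 roi_ref=patch.roi_ref, offset=patch.offset)


LABEL_TO_INT = {"Normal": 0, "Tumor": 1}


def _to_patchset(patches: List[Patch], size: int) -> PatchSet:
    if not patches:
        return PatchSet(
            pixels=np.zeros((0, size, size), np.float32),
            labels=np.zeros(0, int),
            roi_refs=np.zeros(0, int),
            offsets=np.zeros((0, 2), int),
        )
    return PatchSet(
        pixels=np.stack([p.pixels for p in patches]).astype(np.float32),
        labels=np.array([LABEL_TO_INT[p.label] for p in patches]),
        roi_refs=np.array([p.roi_ref for p in patches]),
        offsets=np.array([p.offset for p in patches]),
    )


def build_patch_dataset(
    rois: Sequence[Roi],
    split: SplitAssignment,
    counts: Optional[Dict[str, int]] = None,
    size: int = PATCH_SIZE,
    seed: int = 0,
) -> Dict[str, PatchSet]:
    """Sample per-class patch counts from every ROI, grouped by split."""
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    if any(c <= 0 for c in counts.values()):
        raise ParameterError(f"patch counts must be positive: {counts}")
    rng = np.random.default_rng(seed)
    per_split: Dict[str, List[Patch]] = {s: [] for s in SPLITS}
    for roi_ref in sorted(split.assignment):
        roi = rois[roi_ref]
        n = counts[roi.label]
        patches = sample_patches(roi, n, size=size, rng=rng, roi_ref=roi_ref)
        per_split[split[roi_ref]].extend(patches)
    return {s: _to_patchset(per_split[s], size) for s in SPLITS}
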