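"""Image preprocessing and ROI extraction.

The chain is fixed: median denoising -> CLAHE enhancement -> window
extraction around an annotated (or random breast-interior) center ->
removal of dark non-breast bands -> bilinear rescale to the canonical
120x120 ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology
from skimage.transform import resize

from .errors import (
    DegenerateRoiError,
    EmptyMaskError,
    ParameterError,
    SamplingError,
    SizeError,
)
from .mias_io import AbnormalityAnnotation, MammogramImage

ROI_SIDE = 120
ROI_HALF_SIDE = 60


@dataclass(frozen=True)
class BreastMask:
    """Binary breast-tissue mask with the source image's dimensions."""

    mask: np.ndarray  # (H, W) bool

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.mask.shape)


@dataclass(frozen=True)
class Roi:
    """A preprocessed 120x120 region with a binary label.

    ``annotation_ref`` is the index of the source annotation record, or
    ``None`` for randomly placed Normal ROIs; ``label`` is Tumor exactly
    when an annotation reference is present.
    """

    pixels: np.ndarray  # (120, 120) uint8
    label: str  # "Normal" | "Tumor"
    image_id: str
    center_row: int
    center_col: int
    annotation_ref: Optional[int] = None

    def __post_init__(self):
        if self.pixels.shape != (ROI_SIDE, ROI_SIDE):
            raise ValueError(f"ROI must be {ROI_SIDE}x{ROI_SIDE}")
        if self.label not in ("Normal", "Tumor"):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "Tumor") != (self.annotation_ref is not None):
            raise ValueError("label must be Tumor iff annotation_ref is present")


def denoise_median(image: MammogramImage, kernel: int = 3) -> MammogramImage:
    """Median-filter the image with a kernel x kernel window (reflect border)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be odd and positive, got {kernel}")
    out = ndimage.median_filter(image.pixels, size=kernel, mode="reflect")
    return MammogramImage(image_id=image.image_id, pixels=out.astype(np.uint8))


def enhance_clahe(
    image: MammogramImage,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> MammogramImage:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` follows the common multiple-of-uniform-height
    convention (2.0 by default) and is converted to the fractional limit
    the underlying implementation expects.
    """
    if clip_limit <= 0:
        raise ParameterError(f"clip_limit must be positive, got {clip_limit}")
    if len(tile_grid) != 2 or min(tile_grid) < 1:
        raise ParameterError(f"invalid tile grid {tile_grid}")
    h, w = image.pixels.shape
    kernel_size = (max(1, int(np.ceil(h / tile_grid[0]))),
                   max(1, int(np.ceil(w / tile_grid[1]))))
    out = exposure.equalize_adapthist(
        image.pixels, kernel_size=kernel_size, clip_limit=clip_limit / 256.0
    )
    out8 = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return MammogramImage(image_id=image.image_id, pixels=out8)


def compute_breast_mask(
    image: MammogramImage,
    threshold: int = 15,
    closing_radius: int = 5,
) -> BreastMask:
    """Threshold, morphologically close, keep the largest connected component."""
    bright = image.pixels > threshold
    if not bright.any():
        raise EmptyMaskError(f"no pixel above threshold {threshold}")
    closed = morphology.closing(bright, morphology.disk(closing_radius))
    labels, n = ndimage.label(closed)
    if n == 0:  # closing cannot remove all pixels, but guard anyway
        raise EmptyMaskError("mask vanished after morphological closing")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    return BreastMask(mask=labels == keep)


def annotation_to_rowcol(
    ann: AbnormalityAnnotation, image_height: int
) -> tuple[int, int]:
    """Convert bottom-left-origin (x, y) to top-left-origin (row, col)."""
    if not ann.has_coordinates:
        raise ParameterError(f"annotation for {ann.image_id} has no coordinates")
    return (image_height - 1) - ann.center_y, ann.center_x


def extract_window(
    image: MammogramImage,
    center_row: int,
    center_col: int,
    half_side: int = ROI_HALF_SIDE,
) -> np.ndarray:
    """Cut the (2*half_side)^2 window at the center, shifted inside if it
    overruns the image border."""
    if half_side < 1:
        raise ParameterError(f"half_side must be >= 1, got {half_side}")
    side = 2 * half_side
    h, w = image.pixels.shape
    if h < side or w < side:
        raise SizeError(f"image {h}x{w} smaller than {side}x{side} window")
    top = int(np.clip(center_row - half_side, 0, h - side))
    left = int(np.clip(center_col - half_side, 0, w - side))
    return image.pixels[top : top + side, left : left + side].copy()


def crop_nonbreast(
    window: np.ndarray, dark_threshold: int = 10, dark_fraction: float = 0.95
) -> np.ndarray:
    """Strip leading/trailing rows and columns that are almost entirely dark."""
    if window.size == 0:
        raise ParameterError("empty window")
    dark = window <= dark_threshold
    row_dark = dark.mean(axis=1) > dark_fraction
    col_dark = dark.mean(axis=0) > dark_fraction
    if row_dark.all() or col_dark.all():
        raise DegenerateRoiError("window entirely dark after cropping")
    rows = np.flatnonzero(~row_dark)
    cols = np.flatnonzero(~col_dark)
    return window[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def rescale_roi(grid: np.ndarray, target: int = ROI_SIDE) -> np.ndarray:
    """Bilinear rescale to target x target, clipped to [0, 255] uint8."""
    if grid.size == 0:
        raise ParameterError("empty grid")
    out = resize(
        grid.astype(np.float64),
        (target, target),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def random_roi_center(
    mask: BreastMask,
    half_side: int,
    rng: np.random.Generator,
    min_breast_fraction: float = 0.5,
    max_retries: int = 1000,
) -> tuple[int, int]:
    """Uniformly sample a mask-true pixel whose clamped window is at least
    half inside the breast."""
    m = mask.mask
    h, w = m.shape
    side = 2 * half_side
    if h < side or w < side:
        raise SizeError(f"mask {h}x{w} smaller than {side}x{side} window")
    candidates = np.argwhere(m)
    if len(candidates) == 0:
        raise SamplingError("empty breast mask")
    area = side * side
    for _ in range(max_retries):
        r, c = candidates[rng.integers(len(candidates))]
        top = int(np.clip(r - half_side, 0, h - side))
        left = int(np.clip(c - half_side, 0, w - side))
        frac = m[top : top + side, left : left + side].mean()
        if frac >= min_breast_fraction:
            return int(r), int(c)
    raise SamplingError(f"no admissible center after {max_retries} retries")


def preprocess_image(
    image: MammogramImage,
    median_kernel: int = 3,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> MammogramImage:
    """Denoise then enhance (the first half of the chain)."""
    return enhance_clahe(
        denoise_median(image, kernel=median_kernel),
        clip_limit=clip_limit,
        tile_grid=tile_grid,
    )


def extract_roi(
    enhanced: MammogramImage,
    center_row: int,
    center_col: int,
    label: str,
    annotation_ref: Optional[int] = None,
    half_side: int = ROI_HALF_SIDE,
    dark_threshold: int = 10,
) -> Roi:
    """Window -> dark-band crop -> rescale, yielding a canonical ROI."""
    window = extract_window(enhanced, center_row, center_col, half_side)
    cropped = crop_nonbreast(window, dark_threshold=dark_threshold)
    pixels = rescale_roi(cropped, target=ROI_SIDE)
    return Roi(
        pixels=pixels,
        label=label,
        image_id=enhanced.image_id,
        center_row=center_row,
        center_col=center_col,
        annotation_ref=annotation_ref,
    )


def extract_rois(
    images: dict[str, MammogramImage],
    annotations: Sequence[AbnormalityAnnotation],
    seed: int = 0,
    half_side: int = ROI_HALF_SIDE,
    median_kernel: int = 3,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
    mask_threshold: int = 15,
    dark_threshold: int = 10,
    rois_per_normal: int = 1,
) -> list[Roi]:
    """Run the full chain over a dataset.

    Abnormal annotations with coordinates yield one Tumor ROI each at the
    annotated center; every NORM record yields ``rois_per_normal`` Normal
    ROIs at random breast-interior centers.  Degenerate windows are
    skipped.
    """
    rng = np.random.default_rng(seed)
    enhanced_cache: dict[str, MammogramImage] = {}

    def enhanced(image_id: str) -> MammogramImage:
        if image_id not in enhanced_cache:
            enhanced_cache[image_id] = preprocess_image(
                images[image_id],
                median_kernel=median_kernel,
                clip_limit=clip_limit,
                tile_grid=tile_grid,
            )
        return enhanced_cache[image_id]

    rois: list[Roi] = []
    for idx, ann in enumerate(annotations):
        if ann.image_id not in images:
            continue
        img = enhanced(ann.image_id)
        if ann.is_normal:
            mask = compute_breast_mask(img, threshold=mask_threshold)
            for _ in range(rois_per_normal):
                r, c = random_roi_center(mask, half_side, rng)
                try:
                    rois.append(
                        extract_roi(img, r, c, "Normal", None, half_side,
                                    dark_threshold)
                    )
                except DegenerateRoiError:
                    continue
        elif ann.has_coordinates:
            r, c = annotation_to_rowcol(ann, img.height)
            try:
                rois.append(
                    extract_roi(img, r, c, "Tumor", idx, half_side,
                                dark_threshold)
                )
            except DegenerateRoiError:
                continue
    return rois
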