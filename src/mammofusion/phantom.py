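"""Synthetic MIAS-format mammogram generator.

Emits breast-shaped textured 8-bit images with optional annotated bright
lesions and salt-and-pepper noise, plus the matching plain-text
annotation file, so the whole pipeline runs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .mias_io import (
    AbnormalityAnnotation,
    MammogramImage,
    write_info_file,
    write_pgm,
)


@dataclass(frozen=True)
class PhantomConfig:
    n_normal: int = 10
    n_abnormal: int = 10
    image_side: int = 256
    lesion_radius_range: tuple[int, int] = (8, 40)
    lesion_contrast: int = 60
    lesion_smoothness: float = 0.85  # fraction of texture obscured by the mass
    texture_scale: float = 6.0
    texture_amplitude: float = 12.0
    background_level: int = 3
    breast_level: int = 120
    impulse_noise_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ParameterError("counts must be non-negative")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi <= self.image_side // 4):
            raise ParameterError(
                f"radius range {self.lesion_radius_range} outside "
                f"(0, {self.image_side // 4}]"
            )
        if not (0 <= self.impulse_noise_rate < 0.5):
            raise ParameterError("impulse noise rate must lie in [0, 0.5)")


def _breast_region(side: int) -> np.ndarray:
    """Half-ellipse breast anchored on the left edge, as in a mediolateral
    view: True inside the breast."""
    rows, cols = np.mgrid[0:side, 0:side]
    cy, cx = side * 0.5, 0.0
    ry, rx = side * 0.44, side * 0.62
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _texture(side: int, scale: float, amplitude: float,
             rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((side, side))
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    sd = smooth.std()
    return smooth * (amplitude / sd) if sd > 0 else smooth


def _lesion_profile(side: int, row: int, col: int, radius: int) -> np.ndarray:
    """Unit-peak blob: flat plateau out to 0.6*radius, then a cosine taper
    to zero at the annotated radius (soft mass-like margin)."""
    rows, cols = np.mgrid[0:side, 0:side]
    r = np.hypot(rows - row, cols - col)
    plateau = 0.6 * radius
    taper = 0.5 * (1.0 + np.cos(np.pi * (r - plateau) / (radius - plateau)))
    return np.where(r <= plateau, 1.0, np.where(r <= radius, taper, 0.0))


def generate_image(
    config: PhantomConfig,
    rng: np.random.Generator,
    with_lesion: bool,
    image_id: str,
) -> tuple[MammogramImage, AbnormalityAnnotation]:
    """Generate one phantom mammogram and its annotation record."""
    side = config.image_side
    breast = _breast_region(side)
    img = np.full((side, side), float(config.background_level))
    img[breast] = config.breast_level
    texture = _texture(side, config.texture_scale, config.texture_amplitude, rng)

    tissue = ("F", "G", "D")[rng.integers(3)]
    lesion = None
    if with_lesion:
        lo, hi = config.lesion_radius_range
        radius = int(rng.integers(lo, hi + 1))
        # keep the whole lesion circle comfortably inside the breast
        interior = ndimage.distance_transform_edt(breast) > radius + 6
        candidates = np.argwhere(interior)
        row, col = (int(v) for v in candidates[rng.integers(len(candidates))])
        lesion = _lesion_profile(side, row, col, radius)
        # dense mass: brighter, and it obscures the parenchymal texture
        texture = texture * (1.0 - config.lesion_smoothness * lesion)
        img += config.lesion_contrast * lesion
    img += np.where(breast, texture, 0.0)
    if with_lesion:
        ann = AbnormalityAnnotation(
            image_id=image_id,
            background_tissue=tissue,
            abnorm_class="CIRC",
            severity=("B", "M")[rng.integers(2)],
            center_x=col,
            center_y=(side - 1) - row,
            radius=radius,
        )
    else:
        ann = AbnormalityAnnotation(
            image_id=image_id, background_tissue=tissue, abnorm_class="NORM"
        )

    if config.impulse_noise_rate > 0:
        u = rng.random((side, side))
        img[u < config.impulse_noise_rate / 2] = 0
        img[(u >= config.impulse_noise_rate / 2)
            & (u < config.impulse_noise_rate)] = 255

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return MammogramImage(image_id=image_id, pixels=pixels), ann


def generate_dataset(
    config: PhantomConfig, out_dir=None
) -> tuple[list[MammogramImage], list[AbnormalityAnnotation]]:
    """Generate the full phantom dataset; optionally write PGM files and
    the annotation file under ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    images: list[MammogramImage] = []
    annotations: list[AbnormalityAnnotation] = []
    n_total = config.n_normal + config.n_abnormal
    width = max(3, len(str(max(n_total, 1))))
    for i in range(n_total):
        with_lesion = i >= config.n_normal
        image_id = f"syn{i + 1:0{width}d}"
        img, ann = generate_image(config, rng, with_lesion, image_id)
        images.append(img)
        annotations.append(ann)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in images:
            write_pgm(img, out / f"{img.image_id}.pgm")
        write_info_file(annotations, out / "info.txt")
    return images, annotations
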