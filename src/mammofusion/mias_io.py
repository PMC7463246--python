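"""Readers/writers for MIAS-style archives: 8-bit PGM images plus the
plain-text annotation file.

The annotation file has one whitespace-separated record per line:

    <image_id> <tissue F|G|D> <class> [<severity B|M> [<x> <y> <radius>]]

Lines may have 3 fields (``NORM``), 4 fields (abnormal class without
coordinates) or 7 fields (full annotation).  ``#``-prefixed lines are
comments.  Coordinates use a bottom-left origin, as in the original
archive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InfoParseError, PgmFormatError

BACKGROUND_TISSUES = ("F", "G", "D")
ABNORMALITY_CLASSES = ("CALC", "CIRC", "SPIC", "MISC", "ARCH", "ASYM", "NORM")
SEVERITIES = ("B", "M")


@dataclass(frozen=True)
class MammogramImage:
    """A single grayscale mammogram with 8-bit intensities."""

    image_id: str
    pixels: np.ndarray  # (H, W) uint8

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class AbnormalityAnnotation:
    """One annotated abnormality (bottom-left-origin coordinates)."""

    image_id: str
    background_tissue: str
    abnorm_class: str
    severity: Optional[str] = None
    center_x: Optional[int] = None
    center_y: Optional[int] = None
    radius: Optional[int] = None

    def __post_init__(self):
        if self.background_tissue not in BACKGROUND_TISSUES:
            raise ValueError(f"unknown tissue {self.background_tissue!r}")
        if self.abnorm_class not in ABNORMALITY_CLASSES:
            raise ValueError(f"unknown class {self.abnorm_class!r}")
        if self.severity is not None and self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        coords = (self.center_x, self.center_y, self.radius)
        if any(c is not None for c in coords) and any(c is None for c in coords):
            raise ValueError("center_x, center_y, radius must be given together")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def has_coordinates(self) -> bool:
        return self.center_x is not None

    @property
    def is_normal(self) -> bool:
        return self.abnorm_class == "NORM"


def _parse_int(token: str, lineno: int, what: str) -> int:
    if not re.fullmatch(r"[+-]?\d+", token):
        raise InfoParseError(lineno, f"non-numeric {what}: {token!r}")
    return int(token)


def read_info_file(path) -> list[AbnormalityAnnotation]:
    """Parse an annotation file into one record per non-comment line."""
    records: list[AbnormalityAnnotation] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (3, 4, 7):
            raise InfoParseError(
                lineno, f"expected 3, 4 or 7 fields, got {len(fields)}"
            )
        image_id, tissue, abnorm_class = fields[:3]
        severity = fields[3] if len(fields) >= 4 else None
        cx = cy = radius = None
        if len(fields) == 7:
            cx = _parse_int(fields[4], lineno, "center x")
            cy = _parse_int(fields[5], lineno, "center y")
            radius = _parse_int(fields[6], lineno, "radius")
        try:
            rec = AbnormalityAnnotation(
                image_id=image_id,
                background_tissue=tissue,
                abnorm_class=abnorm_class,
                severity=severity,
                center_x=cx,
                center_y=cy,
                radius=radius,
            )
        except ValueError as exc:
            raise InfoParseError(lineno, str(exc)) from exc
        records.append(rec)
    return records


def write_info_file(records: Sequence[AbnormalityAnnotation], path) -> None:
    """Write records so that :func:`read_info_file` round-trips exactly."""
    lines = []
    for rec in records:
        fields = [rec.image_id, rec.background_tissue, rec.abnorm_class]
        if rec.severity is not None:
            fields.append(rec.severity)
        if rec.has_coordinates:
            fields += [str(rec.center_x), str(rec.center_y), str(rec.radius)]
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def _read_pgm_tokens(data: bytes, n: int, pos: int) -> tuple[list[int], int]:
    """Read *n* ASCII integer tokens from ``data`` starting at ``pos``,
    skipping whitespace and ``#`` comments; returns (tokens, new position)."""
    tokens: list[int] = []
    size = len(data)
    while len(tokens) < n:
        while pos < size and data[pos : pos + 1].isspace():
            pos += 1
        if pos < size and data[pos : pos + 1] == b"#":
            while pos < size and data[pos : pos + 1] not in (b"\n", b"\r"):
                pos += 1
            continue
        start = pos
        while pos < size and not data[pos : pos + 1].isspace():
            pos += 1
        tok = data[start:pos]
        if not tok:
            raise PgmFormatError("truncated PGM header")
        try:
            tokens.append(int(tok))
        except ValueError as exc:
            raise PgmFormatError(f"non-numeric header token {tok!r}") from exc
    return tokens, pos


def read_pgm(path, image_id: Optional[str] = None) -> MammogramImage:
    """Read a binary (P5) or ASCII (P2) 8-bit PGM file."""
    path = Path(path)
    data = path.read_bytes()
    magic = data[:2]
    if magic not in (b"P2", b"P5"):
        raise PgmFormatError(f"not a PGM file (magic {magic!r})")
    (width, height, maxval), pos = _read_pgm_tokens(data, 3, 2)
    if maxval > 255:
        raise PgmFormatError(f"unsupported bit depth (maxval {maxval} > 255)")
    if width < 1 or height < 1:
        raise PgmFormatError("non-positive image dimensions")
    n = width * height
    if magic == b"P5":
        pos += 1  # single whitespace byte after maxval
        raster = data[pos : pos + n]
        if len(raster) != n:
            raise PgmFormatError("truncated PGM raster")
        pixels = np.frombuffer(raster, dtype=np.uint8).reshape(height, width)
    else:
        values, _ = _read_pgm_tokens(data, n, pos)
        arr = np.asarray(values)
        if arr.min() < 0 or arr.max() > maxval:
            raise PgmFormatError("pixel value out of range")
        pixels = arr.astype(np.uint8).reshape(height, width)
    return MammogramImage(image_id=image_id or path.stem, pixels=pixels.copy())


def write_pgm(image: MammogramImage, path) -> None:
    """Write a binary (P5) 8-bit PGM file."""
    header = f"P5\n{image.width} {image.height}\n255\n".encode("ascii")
    Path(path).write_bytes(header + image.pixels.tobytes())
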