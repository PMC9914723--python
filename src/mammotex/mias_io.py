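"""PGM image I/O and mini-MIAS-style metadata tables.

Images are 8-bit grayscale rasters stored as numpy ``uint8`` arrays
(top-left origin, row-major, ``x`` = column, ``y`` = row). The metadata
dialect mirrors the mini-MIAS info file: whitespace-separated rows of

    id  tissue_code  class_code  [severity  x  y  radius]

where the source y coordinate uses a bottom-left origin and is flipped to
the raster convention on ingest (``y_internal = height - 1 - y_file``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GrayImage",
    "MammogramRecord",
    "PGMFormatError",
    "MetadataError",
    "read_pgm",
    "write_pgm",
    "read_metadata",
    "write_metadata",
    "records_to_csv",
]

#: A grayscale image: 2-D uint8 array, intensities 0-255.
GrayImage = np.ndarray


class PGMFormatError(ValueError):
    """Malformed PGM file (bad magic, maxval, or truncated data)."""


class MetadataError(ValueError):
    """Malformed metadata row."""


# class codes used by the mini-MIAS info file; NORM marks a normal case
_ABNORMAL_CODES = {"CIRC", "SPIC", "MISC", "ARCH", "ASYM", "CALC"}


@dataclass
class MammogramRecord:
    """One case of the study: image identity, labels, lesion geometry.

    ``severity`` is None iff ``tissue_class == "normal"``. Lesion geometry
    may be None for an abnormal case whose source row lacked coordinates;
    such records keep their label but are skipped by lesion-centred ROI
    extraction.
    """

    id: str
    laterality: str  # "left" | "right"
    tissue_class: str  # "normal" | "abnormal"
    severity: Optional[str] = None  # "benign" | "malign" | None
    lesion_center: Optional[tuple[int, int]] = None  # (x, y), raster coords
    lesion_radius: Optional[int] = None
    image: Optional[GrayImage] = None

    def validate(self, height: Optional[int] = None, width: Optional[int] = None) -> list[str]:
        """Return invariant violations (empty list when consistent)."""
        errs = []
        if (self.severity is None) != (self.tissue_class == "normal"):
            errs.append(f"{self.id}: severity must be absent iff normal")
        if (self.lesion_center is None) != (self.lesion_radius is None):
            errs.append(f"{self.id}: lesion center and radius must come together")
        if self.lesion_center is not None and height is not None and width is not None:
            x, y = self.lesion_center
            r = self.lesion_radius
            if not (x - r >= 0 and y - r >= 0 and x + r < width and y + r < height):
                errs.append(f"{self.id}: lesion circle exceeds image bounds")
        return errs


def _next_token(data: bytes, pos: int) -> tuple[bytes, int]:
    """Next whitespace-delimited header token, skipping '#' comments."""
    n = len(data)
    while pos < n:
        c = data[pos : pos + 1]
        if c == b"#":
            while pos < n and data[pos : pos + 1] not in (b"\n", b"\r"):
                pos += 1
        elif c.isspace():
            pos += 1
        else:
            break
    start = pos
    while pos < n and not data[pos : pos + 1].isspace() and data[pos : pos + 1] != b"#":
        pos += 1
    if start == pos:
        raise PGMFormatError("truncated header")
    return data[start:pos], pos


def read_pgm(path) -> GrayImage:
    """Read a P2 (ASCII) or P5 (binary) PGM file with maxval <= 255.

    Header comments (``#`` to end of line) are skipped. Raises
    :class:`PGMFormatError` naming the offending field on malformed input.
    """
    data = Path(path).read_bytes()
    magic, pos = _next_token(data, 0)
    if magic not in (b"P2", b"P5"):
        raise PGMFormatError(f"bad magic number {magic!r}: expected P2 or P5")
    fields = []
    for name in ("width", "height", "maxval"):
        tok, pos = _next_token(data, pos)
        try:
            val = int(tok)
        except ValueError:
            raise PGMFormatError(f"non-integer {name}: {tok!r}") from None
        if val <= 0:
            raise PGMFormatError(f"non-positive {name}: {val}")
        fields.append(val)
    width, height, maxval = fields
    if maxval > 255:
        raise PGMFormatError(f"maxval {maxval} exceeds 255 (only 8-bit supported)")
    n = width * height
    if magic == b"P5":
        pos += 1  # single whitespace byte after maxval
        raster = data[pos : pos + n]
        if len(raster) < n:
            raise PGMFormatError(
                f"truncated pixel data: expected {n} bytes, found {len(raster)}"
            )
        pixels = np.frombuffer(raster, dtype=np.uint8, count=n)
    else:
        tokens = re.sub(rb"#[^\n\r]*", b" ", data[pos:]).split()
        if len(tokens) < n:
            raise PGMFormatError(
                f"truncated pixel data: expected {n} values, found {len(tokens)}"
            )
        try:
            pixels = np.array([int(t) for t in tokens[:n]], dtype=np.int64)
        except ValueError:
            raise PGMFormatError("non-integer pixel value") from None
        if pixels.min() < 0 or pixels.max() > maxval:
            raise PGMFormatError("pixel value outside [0, maxval]")
        pixels = pixels.astype(np.uint8)
    return pixels.reshape(height, width)


def write_pgm(img: GrayImage, path, mode: str = "binary") -> None:
    """Write ``img`` as a P5 (``mode="binary"``) or P2 (``mode="ascii"``) PGM."""
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    h, w = img.shape
    path = Path(path)
    if mode == "binary":
        path.write_bytes(b"P5\n%d %d\n255\n" % (w, h) + img.tobytes())
    elif mode == "ascii":
        lines = "\n".join(" ".join(str(v) for v in row) for row in img)
        path.write_text(f"P2\n{w} {h}\n255\n{lines}\n")
    else:
        raise ValueError(f"unknown mode {mode!r}: expected 'ascii' or 'binary'")


def _laterality_from_id(case_id: str) -> str:
    """Odd id number -> left, even -> right (consecutive mini-MIAS ids are
    the paired views of one subject)."""
    m = re.search(r"(\d+)", case_id)
    if m and int(m.group(1)) % 2 == 0:
        return "right"
    return "left"


def read_metadata(path, image_height: int = 1024) -> list[MammogramRecord]:
    """Parse a mini-MIAS-dialect info table into records (no pixel data).

    The file's bottom-left-origin y coordinates are flipped to the raster
    convention using ``image_height``. Abnormal rows missing geometry are
    retained with a warning; unknown severity codes raise
    :class:`MetadataError`.
    """
    records = []
    n_missing = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) < 3:
            raise MetadataError(f"line {lineno}: expected at least 3 columns")
        case_id, _tissue_code, class_code = toks[0], toks[1], toks[2]
        laterality = _laterality_from_id(case_id)
        if class_code == "NORM":
            records.append(MammogramRecord(case_id, laterality, "normal"))
            continue
        if class_code not in _ABNORMAL_CODES:
            raise MetadataError(f"line {lineno}: unknown class code {class_code!r}")
        if len(toks) < 4:
            raise MetadataError(f"line {lineno}: abnormal row missing severity")
        sev_code = toks[3]
        if sev_code not in ("B", "M"):
            raise MetadataError(f"line {lineno}: unknown severity code {sev_code!r}")
        severity = "benign" if sev_code == "B" else "malign"
        center = radius = None
        if len(toks) >= 7:
            x, y_file, radius = int(toks[4]), int(toks[5]), int(toks[6])
            center = (x, image_height - 1 - y_file)
        else:
            n_missing += 1
            log.warning("%s: abnormal row without lesion geometry", case_id)
        records.append(
            MammogramRecord(case_id, laterality, "abnormal", severity, center, radius)
        )
    if n_missing:
        log.info("%d abnormal record(s) lack lesion geometry", n_missing)
    return records


def write_metadata(records: list[MammogramRecord], path, image_height: int = 1024) -> None:
    """Emit records in the mini-MIAS dialect (y flipped back to bottom-left)."""
    lines = []
    for r in records:
        if r.tissue_class == "normal":
            lines.append(f"{r.id} G NORM")
        else:
            sev = "B" if r.severity == "benign" else "M"
            if r.lesion_center is None:
                lines.append(f"{r.id} G CIRC {sev}")
            else:
                x, y = r.lesion_center
                shape = "CIRC" if r.severity == "benign" else "SPIC"
                lines.append(
                    f"{r.id} G {shape} {sev} {x} {image_height - 1 - y} {r.lesion_radius}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def records_to_csv(records: list[MammogramRecord], path) -> None:
    """Export records with header id,laterality,tissue_class,severity,x,y,radius."""
    rows = ["id,laterality,tissue_class,severity,x,y,radius"]
    for r in records:
        x, y = r.lesion_center if r.lesion_center else ("", "")
        rows.append(
            f"{r.id},{r.laterality},{r.tissue_class},{r.severity or ''},"
            f"{x},{y},{r.lesion_radius if r.lesion_radius is not None else ''}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
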