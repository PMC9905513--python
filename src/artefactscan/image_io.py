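"""Raster-image and grid-coordinate primitives.

Images are plain :class:`numpy.ndarray` objects in scikit-image convention:
``(rows, cols)`` for grayscale, ``(rows, cols, 3)`` for RGB, dtype ``uint8``
for stored pixels (floats are allowed after conversion steps).  All pixel
coordinates are 0-based ``(row, col)`` with the origin at the top-left corner;
boxes are half-open.

A large photograph can be referenced through a coarse cell grid: cells are
numbered row-major starting at 1, and each cell is further subdivided into
four equal vertical strips (columns ``A``–``D``, left to right) and three
equal horizontal strips (rows ``1``–``3``, top to bottom), yielding labels
such as ``"63C3"``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ImageFormatError

__all__ = [
    "PixelBox",
    "GridRef",
    "read_image",
    "write_image",
    "to_grayscale",
    "pixel_to_gridref",
    "gridref_bounds",
    "annotate_boxes",
]

logger = logging.getLogger(__name__)

_SUBCOLS = "ABCD"
_LABEL_RE = re.compile(r"^(\d+)([A-D])([1-3])$")


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned pixel rectangle, half-open, ``(top, left)`` anchored."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("box must contain at least one pixel")
        if self.top < 0 or self.left < 0:
            raise ValueError("box anchor must be non-negative")

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    def fits(self, shape: tuple[int, ...]) -> bool:
        return self.bottom <= shape[0] and self.right <= shape[1]

    def centre(self) -> tuple[int, int]:
        return (self.top + self.height // 2, self.left + self.width // 2)


@dataclass(frozen=True)
class GridRef:
    """Cell + subcell reference on a P×Q grid (cells numbered row-major from 1)."""

    cell: int
    subcolumn: str
    subrow: int

    def __post_init__(self) -> None:
        if self.cell < 1:
            raise ValueError("cell numbering starts at 1")
        if self.subcolumn not in _SUBCOLS:
            raise ValueError(f"subcolumn must be one of {_SUBCOLS!r}")
        if self.subrow not in (1, 2, 3):
            raise ValueError("subrow must be 1, 2 or 3")

    @property
    def label(self) -> str:
        return f"{self.cell}{self.subcolumn}{self.subrow}"

    @classmethod
    def from_label(cls, label: str) -> "GridRef":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"not a grid label: {label!r}")
        return cls(int(m.group(1)), m.group(2), int(m.group(3)))


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF file into an 8-bit image array.

    Paletted and RGBA inputs are converted to RGB; 16-bit inputs are rescaled
    to 8-bit with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64)
                logger.warning("rescaling 16-bit image %s to 8-bit", path)
                arr = np.floor(arr / 65535.0 * 255.0 + 0.5)
                return np.clip(arr, 0, 255).astype(np.uint8)
            if im.mode == "L":
                return np.asarray(im, dtype=np.uint8)
            converted = im.convert("RGB")
            return np.asarray(converted, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"unreadable or unsupported image: {path}") from exc


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an 8-bit grayscale or RGB array as PNG or TIFF (by extension)."""
    path = Path(path)
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        raise ValueError("only 8-bit images are written; convert first")
    if arr.ndim not in (2, 3):
        raise ValueError("image must be 2-D or 3-D")
    Image.fromarray(arr).save(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to single-channel using BT.601 luma weights.

    ``y = 0.299 R + 0.587 G + 0.114 B`` rounded half-up.  Grayscale input is
    returned unchanged (idempotent).
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected 1 or 3 channels, got shape {arr.shape}")
    y = (
        0.299 * arr[..., 0].astype(np.float64)
        + 0.587 * arr[..., 1].astype(np.float64)
        + 0.114 * arr[..., 2].astype(np.float64)
    )
    return np.floor(y + 0.5).astype(np.uint8)


def pixel_to_gridref(
    row: int,
    col: int,
    shape: tuple[int, int],
    grid: tuple[int, int] = (10, 10),
) -> GridRef:
    """Map a pixel to its grid cell and A–D / 1–3 subcell.

    The image is split into ``grid = (P, Q)`` equal cells (strips are
    half-open, so a pixel on an exact boundary belongs to the strip that
    starts there).  Cells are numbered row-major from 1 at the top-left.
    """
    M, N = int(shape[0]), int(shape[1])
    P, Q = int(grid[0]), int(grid[1])
    if P < 1 or Q < 1:
        raise ValueError("grid must have at least one cell per axis")
    if not (0 <= row < M and 0 <= col < N):
        raise ValueError(f"pixel ({row}, {col}) outside image {M}x{N}")
    # exact integer strip arithmetic: strip k covers [k*M/P, (k+1)*M/P)
    cell_r = row * P // M
    cell_c = col * Q // N
    cell = cell_r * Q + cell_c + 1
    subrow = row * P * 3 // M - cell_r * 3
    subcol = col * Q * 4 // N - cell_c * 4
    return GridRef(cell, _SUBCOLS[subcol], subrow + 1)


def _strip_bounds(k: int, total: int, strips: int) -> tuple[int, int]:
    # pixels p with p*strips//total == k, i.e. p in [ceil(k*T/S), ceil((k+1)*T/S))
    lo = -(-k * total // strips)
    hi = -(-(k + 1) * total // strips)
    return lo, hi


def gridref_bounds(
    ref: GridRef,
    shape: tuple[int, int],
    grid: tuple[int, int] = (10, 10),
) -> PixelBox:
    """Pixel rectangle covered by a grid reference (inverse of the mapping)."""
    M, N = int(shape[0]), int(shape[1])
    P, Q = int(grid[0]), int(grid[1])
    if not (1 <= ref.cell <= P * Q):
        raise ValueError(f"cell {ref.cell} outside {P}x{Q} grid")
    cell_r, cell_c = divmod(ref.cell - 1, Q)
    sub_r = ref.subrow - 1
    sub_c = _SUBCOLS.index(ref.subcolumn)
    r_lo, r_hi = _strip_bounds(cell_r * 3 + sub_r, M, P * 3)
    c_lo, c_hi = _strip_bounds(cell_c * 4 + sub_c, N, Q * 4)
    if r_hi <= r_lo or c_hi <= c_lo:
        raise ValueError(f"grid cell {ref.label} covers no whole pixel in {M}x{N}")
    return PixelBox(r_lo, c_lo, r_hi - r_lo, c_hi - c_lo)


def annotate_boxes(
    img: np.ndarray,
    boxes: list[PixelBox],
    colour: int | tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Return a copy of ``img`` with 1-px box outlines burned in.

    The input is never modified.  Default outline is 255 on grayscale and red
    on RGB images.
    """
    arr = np.asarray(img)
    out = arr.copy()
    if colour is None:
        colour = 255 if arr.ndim == 2 else (255, 0, 0)
    for box in boxes:
        if not box.fits(arr.shape):
            raise ValueError(f"box {box} outside image of shape {arr.shape[:2]}")
        out[box.top, box.left : box.right] = colour
        out[box.bottom - 1, box.left : box.right] = colour
        out[box.top : box.bottom, box.left] = colour
        out[box.top : box.bottom, box.right - 1] = colour
    return out
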