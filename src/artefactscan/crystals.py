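"""Pigment-crystal detection and spatial statistics on tiled micrographs.

Crystals are segmented per colour class with hue/saturation/value gates,
located in micrometre coordinates via the mosaic's stage geometry, and
deduplicated where adjacent tiles overlap.  Inter-crystal distances are then
summarized per colour pair (same-colour or cross-colour), either as
nearest-neighbour distances or over all pairs, restricted by default to each
crystal's own tile plus the four edge-adjacent tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.color import rgb2hsv

from .errors import GeometryError, InsufficientDataError, LowContrastWarning

__all__ = [
    "ColourClassSpec",
    "default_colour_specs",
    "TileMosaic",
    "Crystal",
    "DistancePairStats",
    "DensityReport",
    "classify_colours",
    "detect_crystals",
    "dedup_overlap",
    "pair_distances",
    "distance_histogram",
    "density",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

#: Fraction of pixels below which a class mask triggers a low-contrast warning.
LOW_COVERAGE_FRACTION = 0.0005
#: Default centroid match radius for overlap deduplication, micrometres.
DEFAULT_MATCH_RADIUS_UM = 2.0
#: Default minimum component size, pixels.
DEFAULT_MIN_AREA_PX = 4


@dataclass(frozen=True)
class ColourClassSpec:
    """Hue/saturation/value gate defining one pigment colour class.

    ``hue_ranges`` are half-open degree intervals in [0, 360); an interval
    with ``lo > hi`` wraps around 0 (e.g. red ``(330, 20)``).
    """

    name: str
    hue_ranges: tuple[tuple[float, float], ...]
    sat_min: float = 0.3
    val_min: float = 0.2

    def __post_init__(self) -> None:
        if not self.hue_ranges:
            raise ValueError("at least one hue interval required")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_min <= 1):
            raise ValueError("sat_min and val_min must lie in [0, 1]")

    def hue_member(self, hue_deg: np.ndarray) -> np.ndarray:
        member = np.zeros(np.shape(hue_deg), dtype=bool)
        for lo, hi in self.hue_ranges:
            if lo <= hi:
                member |= (hue_deg >= lo) & (hue_deg < hi)
            else:
                member |= (hue_deg >= lo) | (hue_deg < hi)
        return member


def default_colour_specs() -> list[ColourClassSpec]:
    """Blue / red / yellow gates for ultramarine, vermilion and chrome yellow."""
    return [
        ColourClassSpec("blue", ((190.0, 270.0),)),
        ColourClassSpec("red", ((330.0, 20.0),)),
        ColourClassSpec("yellow", ((40.0, 70.0),)),
    ]


@dataclass(frozen=True)
class TileMosaic:
    """Geometry of a grid of overlapping micrographs acquired on a stage.

    Adjacent tile origins are separated by ``step = extent * (1 - overlap)``
    per axis; the global micrometre coordinate of a tile-local point is the
    tile origin plus ``local_px / scale``.
    """

    layout: tuple[int, int]  # (rows, cols) of tiles
    tile_px: tuple[int, int]  # (height, width) of one tile, pixels
    scale: float  # pixels per micrometre
    overlap_frac: tuple[float, float] = (0.0, 0.0)  # (vertical, horizontal)
    step_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise GeometryError("scale must be positive")
        fy, fx = self.overlap_frac
        if not (0 <= fy < 1 and 0 <= fx < 1):
            raise GeometryError("overlap fractions must lie in [0, 1)")
        if self.step_um is not None:
            ey, ex = self.tile_extent_um
            exp = (ey * (1 - fy), ex * (1 - fx))
            if not np.allclose(self.step_um, exp, rtol=1e-6, atol=1e-9):
                raise GeometryError(
                    f"step_um {self.step_um} inconsistent with extent*(1-overlap) {exp}"
                )

    @property
    def tile_extent_um(self) -> tuple[float, float]:
        return (self.tile_px[0] / self.scale, self.tile_px[1] / self.scale)

    @property
    def step(self) -> tuple[float, float]:
        ey, ex = self.tile_extent_um
        return (ey * (1 - self.overlap_frac[0]), ex * (1 - self.overlap_frac[1]))

    @property
    def extent_um(self) -> tuple[float, float]:
        """Overall (height, width) of the mosaic field in micrometres."""
        rows, cols = self.layout
        sy, sx = self.step
        ey, ex = self.tile_extent_um
        return (sy * (rows - 1) + ey, sx * (cols - 1) + ex)

    def tile_origin_um(self, row: int, col: int) -> tuple[float, float]:
        """Global (x, y) of a tile's top-left corner."""
        rows, cols = self.layout
        if not (0 <= row < rows and 0 <= col < cols):
            raise GeometryError(f"tile ({row}, {col}) outside layout {self.layout}")
        sy, sx = self.step
        return (col * sx, row * sy)

    @property
    def overlap_um(self) -> tuple[float, float]:
        """(vertical, horizontal) width of the shared strip, micrometres."""
        ey, ex = self.tile_extent_um
        return (ey * self.overlap_frac[0], ex * self.overlap_frac[1])


@dataclass(frozen=True)
class Crystal:
    """One segmented pigment particle."""

    centroid_um: tuple[float, float]  # (x, y)
    colour: str
    area_um2: float
    tile: tuple[int, int] | None = None


@dataclass
class DistancePairStats:
    """Inter-crystal distance summary for one colour pair."""

    pair: tuple[str, str]
    mode: Literal["nearest", "all_pairs"]
    distances_um: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return int(self.distances_um.size)

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.distances_um))

    @property
    def sd_um(self) -> float:
        return float(np.std(self.distances_um))


@dataclass(frozen=True)
class DensityReport:
    colour: str
    count: int
    area_um2: float

    @property
    def density(self) -> float:
        return self.count / self.area_um2


def classify_colours(
    img: np.ndarray, specs: Sequence[ColourClassSpec] | None = None
) -> dict[str, np.ndarray]:
    """Split an RGB image into one binary mask per colour class.

    A pixel goes to the first spec (in list order) whose gate contains it, so
    the returned masks are mutually exclusive.  A class covering fewer than
    0.05% of pixels raises a :class:`LowContrastWarning`.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("colour classification needs an RGB image")
    if specs is None:
        specs = default_colour_specs()
    hsv = rgb2hsv(arr)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    assigned = np.zeros(arr.shape[:2], dtype=bool)
    masks: dict[str, np.ndarray] = {}
    for spec in specs:
        member = (
            spec.hue_member(hue)
            & (sat >= spec.sat_min)
            & (val >= spec.val_min)
            & ~assigned
        )
        masks[spec.name] = member
        assigned |= member
        if member.mean() < LOW_COVERAGE_FRACTION:
            warnings.warn(
                f"colour class {spec.name!r} covers "
                f"{member.mean() * 100:.4f}% of pixels; low-contrast crystals "
                "may be missed",
                LowContrastWarning,
                stacklevel=2,
            )
    return masks


def detect_crystals(
    mask: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    scale: float = 1.0,
    colour: str = "unknown",
    tile: tuple[int, int] | None = None,
) -> list[Crystal]:
    """8-connected components of a binary mask as crystals in tile-local µm.

    Centroids are unweighted pixel centroids divided by ``scale``; areas are
    pixel counts over ``scale**2``.  Components below ``min_area_px`` are
    dropped as sub-resolution noise.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    m = np.asarray(mask, dtype=bool)
    labels, n_comp = ndimage.label(m, structure=_EIGHT_CONNECTED)
    if n_comp == 0:
        return []
    idx = np.arange(1, n_comp + 1)
    areas = ndimage.sum_labels(m, labels, index=idx)
    centroids = ndimage.center_of_mass(m, labels, index=idx)
    out = []
    for area, (row, col) in zip(areas, centroids):
        if area < min_area_px:
            continue
        out.append(
            Crystal(
                centroid_um=(col / scale, row / scale),
                colour=colour,
                area_um2=float(area) / scale**2,
                tile=tile,
            )
        )
    return out


def common_area_index(mosaic: TileMosaic) -> float:
    """Mean pairwise overlap fraction between edge-adjacent tiles."""
    rows, cols = mosaic.layout
    fy, fx = mosaic.overlap_frac
    n_h = rows * (cols - 1)
    n_v = (rows - 1) * cols
    if n_h + n_v == 0:
        return 0.0
    return (n_h * fx + n_v * fy) / (n_h + n_v)


def dedup_overlap(
    per_tile: Mapping[tuple[int, int], Sequence[Crystal]],
    mosaic: TileMosaic,
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> tuple[list[Crystal], float]:
    """Merge per-tile crystal lists into one global list, dropping re-observations.

    Tiles are visited row-major; a crystal whose centroid lies in an overlap
    strip shared with an already-visited neighbour and that matches a kept
    crystal of the same colour within ``match_radius_um`` is dropped.  The
    strip test is widened by ``match_radius_um`` so that observations of a
    crystal sitting just past a neighbour's border (which that neighbour saw
    as a clipped sliver) are still deduplicated.  Input centroids are
    tile-local µm; output centroids are global µm.  Also returns the
    common-area index (mean adjacent-tile overlap fraction).
    """
    rows, cols = mosaic.layout
    ov_y, ov_x = mosaic.overlap_um
    kept: list[Crystal] = []
    kept_xy: dict[str, list[tuple[float, float]]] = {}
    for (tr, tc) in sorted(per_tile):
        if not (0 <= tr < rows and 0 <= tc < cols):
            raise GeometryError(f"tile ({tr}, {tc}) outside layout {mosaic.layout}")
        x0, y0 = mosaic.tile_origin_um(tr, tc)
        for crystal in sorted(
            per_tile[(tr, tc)], key=lambda c: (c.centroid_um[1], c.centroid_um[0])
        ):
            lx, ly = crystal.centroid_um
            gx, gy = x0 + lx, y0 + ly
            in_prev_strip = (
                tc > 0 and ov_x > 0 and lx < ov_x + match_radius_um
            ) or (tr > 0 and ov_y > 0 and ly < ov_y + match_radius_um)
            if in_prev_strip:
                prior = kept_xy.get(crystal.colour)
                if prior:
                    d2 = (np.asarray(prior) - (gx, gy)) ** 2
                    if np.min(d2.sum(axis=1)) <= match_radius_um**2:
                        continue
            kept.append(
                Crystal(
                    centroid_um=(gx, gy),
                    colour=crystal.colour,
                    area_um2=crystal.area_um2,
                    tile=(tr, tc),
                )
            )
            kept_xy.setdefault(crystal.colour, []).append((gx, gy))
    return kept, common_area_index(mosaic)


def _tiles_adjacent(
    a: tuple[int, int] | None, b: tuple[int, int] | None
) -> bool:
    # missing tile indices disable the neighbourhood restriction for that pair
    if a is None or b is None:
        return True
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) <= 1


def pair_distances(
    crystals: Sequence[Crystal],
    pair: tuple[str, str],
    mode: Literal["nearest", "all_pairs"] = "nearest",
    tile_neighbourhood: bool = True,
) -> DistancePairStats:
    """Euclidean µm distance statistics for a colour pair.

    ``nearest`` (default): per crystal of the first class, the distance to its
    nearest distinct crystal of the second class within its own tile plus the
    four edge-adjacent tiles.  ``all_pairs``: every unordered qualifying pair.
    Set ``tile_neighbourhood=False`` to ignore tile adjacency entirely.
    """
    class_a, class_b = pair
    a_list = [c for c in crystals if c.colour == class_a]
    b_list = a_list if class_b == class_a else [c for c in crystals if c.colour == class_b]
    if class_a == class_b:
        if len(a_list) < 2:
            raise InsufficientDataError(
                f"need >= 2 crystals of {class_a!r}, have {len(a_list)}"
            )
    elif not a_list or not b_list:
        raise InsufficientDataError(
            f"need >= 1 crystal of each of {class_a!r} and {class_b!r}"
        )

    xy_a = np.array([c.centroid_um for c in a_list], dtype=np.float64)
    xy_b = np.array([c.centroid_um for c in b_list], dtype=np.float64)
    dist = cdist(xy_a, xy_b)
    qualify = np.ones(dist.shape, dtype=bool)
    if tile_neighbourhood:
        for i, ca in enumerate(a_list):
            for j, cb in enumerate(b_list):
                qualify[i, j] = _tiles_adjacent(ca.tile, cb.tile)
    if class_a == class_b:
        np.fill_diagonal(qualify, False)

    if mode == "nearest":
        masked = np.where(qualify, dist, np.inf)
        per_crystal = masked.min(axis=1)
        distances = per_crystal[np.isfinite(per_crystal)]
    elif mode == "all_pairs":
        if class_a == class_b:
            sel = np.triu(qualify, k=1)
        else:
            sel = qualify
        distances = dist[sel]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if distances.size == 0:
        raise InsufficientDataError(
            f"no qualifying {class_a!r}-{class_b!r} pairs in the tile neighbourhood"
        )
    return DistancePairStats(pair=pair, mode=mode, distances_um=np.sort(distances))


def distance_histogram(
    stats: DistancePairStats, bins: int | np.ndarray = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a pair's distances; counts always sum to ``stats.n``.

    With integer ``bins``, uses equal-width bins over [0, max distance].
    Returns ``(counts, edges)`` and stores them on ``stats.histogram`` as
    ``(edges, counts)``.
    """
    if stats.n < 1:
        raise InsufficientDataError("no distances to histogram")
    d = stats.distances_um
    if np.isscalar(bins) or isinstance(bins, int):
        hi = float(d.max())
        if hi <= 0:
            hi = 1.0
        counts, edges = np.histogram(d, bins=int(bins), range=(0.0, hi))
    else:
        counts, edges = np.histogram(d, bins=np.asarray(bins, dtype=np.float64))
    stats.histogram = (edges, counts)
    return counts, edges


def density(
    crystals: Iterable[Crystal], colour: str, area_um2: float
) -> DensityReport:
    """Crystals of one colour per µm² of analyzed area."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    count = sum(1 for c in crystals if c.colour == colour)
    return DensityReport(colour=colour, count=count, area_um2=area_um2)
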