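"""Seeded synthetic fixtures: scenes with planted templates, crystal mosaics
and station logs, each with machine-readable ground truth.

Every generator is a pure function of its recipe: a single
``numpy.random.default_rng(seed)`` stream per call, no global state, so
identical recipes give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.draw import ellipse

from .crystals import ColourClassSpec, TileMosaic, default_colour_specs
from .errors import FeasibilityError, PlacementError
from .matching import TemplatePattern

__all__ = [
    "SceneRecipe",
    "MosaicRecipe",
    "LogRecipe",
    "make_template",
    "make_scene",
    "make_mosaic",
    "make_station_log",
    "write_station_log",
]

#: Template sizes used throughout the fixtures (height, width).
DEFAULT_TEMPLATE_SHAPES = ((123, 156), (83, 95))


# ---------------------------------------------------------------------------
# scenes with planted templates


@dataclass(frozen=True)
class SceneRecipe:
    """Recipe for a grayscale scene containing planted template copies."""

    seed: int
    size: tuple[int, int] = (1024, 1024)
    templates: tuple[TemplatePattern, ...] = ()
    k_plants: tuple[int, ...] = ()
    noise_sd: float = 0.0
    brightness_jitter: tuple[float, float] = (0.0, 0.0)  # additive, intensity units
    contrast_jitter: tuple[float, float] = (1.0, 1.0)  # multiplicative
    background: Literal["flat", "blotch"] = "flat"
    background_level: float = 60.0

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.k_plants):
            raise ValueError("templates and k_plants must pair up")
        if any(k < 0 for k in self.k_plants):
            raise ValueError("plant counts cannot be negative")


def make_template(
    seed: int, shape: tuple[int, int] = DEFAULT_TEMPLATE_SHAPES[0], sigma: float = 4.0
) -> np.ndarray:
    """A smooth, non-constant 8-bit pattern to use as a matching template."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=shape)
    smooth = gaussian_filter(noise, sigma=sigma)
    lo, hi = smooth.min(), smooth.max()
    scaled = (smooth - lo) / (hi - lo) * 215.0 + 20.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def _boxes_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ar, ac, ah, aw = a
    br, bc, bh, bw = b
    return ar < br + bh and br < ar + ah and ac < bc + bw and bc < ac + aw


def make_scene(recipe: SceneRecipe) -> tuple[np.ndarray, list[dict]]:
    """Render a scene and return it with its plant ground truth.

    Each plant is a full template copy with per-plant contrast/brightness
    jitter; global Gaussian noise is added last.  Plants never overlap each
    other; failure to place one within ``10 * k`` attempts raises.
    Truth entries are ``{"template_id", "row", "col"}`` (top-left anchors).
    """
    rng = np.random.default_rng(recipe.seed)
    M, N = recipe.size
    if recipe.background == "flat":
        scene = np.full((M, N), recipe.background_level, dtype=np.float64)
    elif recipe.background == "blotch":
        blotch = gaussian_filter(rng.normal(size=(M, N)), sigma=max(8, min(M, N) // 8))
        lo, hi = blotch.min(), blotch.max()
        scene = (blotch - lo) / max(hi - lo, 1e-12) * 50.0 + 40.0
    else:
        raise ValueError(f"unknown background {recipe.background!r}")

    placed: list[tuple[int, int, int, int]] = []
    truth: list[dict] = []
    for tpl, k in zip(recipe.templates, recipe.k_plants):
        m, n = tpl.shape
        if m > M or n > N:
            raise PlacementError(f"template {tpl.template_id!r} larger than scene")
        budget = 10 * max(k, 1)
        placed_k = 0
        attempts = 0
        while placed_k < k:
            if attempts >= budget:
                raise PlacementError(
                    f"could not place {k} copies of {tpl.template_id!r} "
                    f"within {budget} attempts"
                )
            attempts += 1
            r = int(rng.integers(0, M - m + 1))
            s = int(rng.integers(0, N - n + 1))
            box = (r, s, m, n)
            if any(_boxes_overlap(box, other) for other in placed):
                continue
            a = float(rng.uniform(*recipe.contrast_jitter))
            b = float(rng.uniform(*recipe.brightness_jitter))
            patch = np.clip(a * tpl.gray.astype(np.float64) + b, 0.0, 255.0)
            scene[r : r + m, s : s + n] = patch
            placed.append(box)
            truth.append({"template_id": tpl.template_id, "row": r, "col": s})
            placed_k += 1

    if recipe.noise_sd > 0:
        scene = scene + rng.normal(0.0, recipe.noise_sd, size=scene.shape)
    return np.clip(np.floor(scene + 0.5), 0, 255).astype(np.uint8), truth


# ---------------------------------------------------------------------------
# crystal mosaics


@dataclass(frozen=True)
class MosaicRecipe:
    """Recipe for a tiled crystal mosaic with a hardcore point process.

    ``class_intensity`` maps colour-class names to crystals per µm²; the
    default 0.01/µm² for blue mirrors a packing of ~20 crystals per 2000 µm².
    ``planted`` bypasses random sampling with explicit ``(x_um, y_um, colour)``
    positions.
    """

    seed: int
    layout: tuple[int, int] = (2, 2)
    tile_px: tuple[int, int] = (400, 400)
    scale: float = 4.0  # px per µm
    overlap_frac: tuple[float, float] = (0.15, 0.15)
    class_intensity: tuple[tuple[str, float], ...] = (("blue", 0.01),)
    min_sep_um: float = 5.0
    radius_um: tuple[float, float] = (1.0, 2.0)
    specs: tuple[ColourClassSpec, ...] = ()
    planted: tuple[tuple[float, float, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.radius_um[0] <= 0 or self.radius_um[1] < self.radius_um[0]:
            raise ValueError("radius range must be positive and ordered")


def _class_colour_rgb(
    spec: ColourClassSpec, rng: np.random.Generator
) -> tuple[int, int, int]:
    """A renderable RGB colour inside the class's hue gate, jittered."""
    lo, hi = spec.hue_ranges[0]
    span = (hi - lo) % 360.0 or 360.0
    hue = (lo + span * rng.uniform(0.25, 0.75)) % 360.0
    sat = rng.uniform(max(spec.sat_min + 0.2, 0.6), 0.95)
    val = rng.uniform(max(spec.val_min + 0.3, 0.6), 0.95)
    rgb = hsv2rgb(np.array([[[hue / 360.0, sat, val]]]))[0, 0]
    return tuple(int(v) for v in np.floor(rgb * 255.0 + 0.5))


def _sample_hardcore(
    rng: np.random.Generator,
    extent: tuple[float, float],
    margin: float,
    targets: Sequence[tuple[str, int]],
    min_sep: float,
) -> list[tuple[float, float, str]]:
    """Sequential rejection sampling with a global minimum separation."""
    height, width = extent
    if width - 2 * margin <= 0 or height - 2 * margin <= 0:
        raise FeasibilityError("field too small for the crystal radius margin")
    pts: list[tuple[float, float, str]] = []
    coords = np.empty((0, 2))
    n_total = sum(n for _, n in targets)
    max_attempts = 1000 + 200 * n_total
    attempts = 0
    for name, n in targets:
        for _ in range(n):
            while True:
                if attempts >= max_attempts:
                    raise FeasibilityError(
                        f"could not place {n_total} crystals at min separation "
                        f"{min_sep} µm within {max_attempts} attempts"
                    )
                attempts += 1
                x = rng.uniform(margin, width - margin)
                y = rng.uniform(margin, height - margin)
                if coords.size:
                    d2 = ((coords - (x, y)) ** 2).sum(axis=1)
                    if d2.min() < min_sep**2:
                        continue
                pts.append((x, y, name))
                coords = np.vstack([coords, (x, y)])
                break
    return pts


def make_mosaic(
    recipe: MosaicRecipe,
) -> tuple[dict[tuple[int, int], np.ndarray], TileMosaic, list[dict]]:
    """Render mosaic tiles and return them with geometry and ground truth.

    Crystals are filled ellipses in jittered class colours on a dark
    background; a crystal intersecting several tiles is rendered in each.
    Truth entries carry global centroids, colour, radii, and the list of
    tiles whose extent contains the centroid.
    """
    rng = np.random.default_rng(recipe.seed)
    mosaic = TileMosaic(
        layout=recipe.layout,
        tile_px=recipe.tile_px,
        scale=recipe.scale,
        overlap_frac=recipe.overlap_frac,
    )
    specs = {s.name: s for s in (recipe.specs or default_colour_specs())}
    height_um, width_um = mosaic.extent_um
    r_lo, r_hi = recipe.radius_um

    if recipe.planted is not None:
        points = list(recipe.planted)
    else:
        area = height_um * width_um
        targets = [
            (name, int(round(lam * area))) for name, lam in recipe.class_intensity
        ]
        points = _sample_hardcore(
            rng, (height_um, width_um), r_hi, targets, recipe.min_sep_um
        )

    crystals = []
    for x, y, name in points:
        if name not in specs:
            raise ValueError(f"no colour spec for class {name!r}")
        ry = float(rng.uniform(r_lo, r_hi))
        rx = float(rng.uniform(r_lo, r_hi))
        rgb = _class_colour_rgb(specs[name], rng)
        crystals.append((x, y, name, ry, rx, rgb))

    th, tw = recipe.tile_px
    rows, cols = recipe.layout
    ey, ex = mosaic.tile_extent_um
    tiles: dict[tuple[int, int], np.ndarray] = {}
    truth: list[dict] = []
    for tr in range(rows):
        for tc in range(cols):
            tile = np.full((th, tw, 3), 30, dtype=np.uint8)
            x0, y0 = mosaic.tile_origin_um(tr, tc)
            for x, y, name, ry, rx, rgb in crystals:
                row_px = (y - y0) * recipe.scale
                col_px = (x - x0) * recipe.scale
                if (
                    row_px < -ry * recipe.scale - 1
                    or row_px > th + ry * recipe.scale
                    or col_px < -rx * recipe.scale - 1
                    or col_px > tw + rx * recipe.scale
                ):
                    continue
                rr, cc = ellipse(
                    row_px, col_px, ry * recipe.scale, rx * recipe.scale, shape=(th, tw)
                )
                tile[rr, cc] = rgb
            tiles[(tr, tc)] = tile

    for x, y, name, ry, rx, _ in crystals:
        observing = []
        for tr in range(rows):
            for tc in range(cols):
                x0, y0 = mosaic.tile_origin_um(tr, tc)
                if x0 <= x < x0 + ex and y0 <= y < y0 + ey:
                    observing.append([tr, tc])
        truth.append(
            {
                "x_um": x,
                "y_um": y,
                "colour": name,
                "radius_y_um": ry,
                "radius_x_um": rx,
                "tiles": observing,
            }
        )
    return tiles, mosaic, truth


# ---------------------------------------------------------------------------
# station logs


@dataclass(frozen=True)
class LogRecipe:
    """Sinusoidal diurnal cycles plus seeded Gaussian noise."""

    seed: int
    days: int = 3
    start: str = "2021-07-01T00:00:00"
    interval_min: int = 10
    means: Mapping[str, float] = field(
        default_factory=lambda: {
            "temperature_c": 23.5,
            "rh_pct": 72.7,
            "co2_ppm": 570.0,
            "light": 150.0,
        }
    )
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {
            "temperature_c": 2.0,
            "rh_pct": 5.0,
            "co2_ppm": 40.0,
            "light": 120.0,
        }
    )
    peak_hours: Mapping[str, float] = field(
        default_factory=lambda: {
            "temperature_c": 15.0,
            "rh_pct": 3.0,
            "co2_ppm": 15.0,
            "light": 12.0,
        }
    )
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.days < 2:
            raise ValueError("need at least 2 days for a diurnal profile")


def make_station_log(recipe: LogRecipe) -> tuple[pd.DataFrame, dict]:
    """Generate a station log and its truth (configured means and peak hours)."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.days * 24 * 60 // recipe.interval_min
    timestamps = pd.date_range(
        recipe.start, periods=n, freq=f"{recipe.interval_min}min"
    )
    hours = timestamps.hour + timestamps.minute / 60.0
    data: dict[str, np.ndarray] = {"timestamp": timestamps}
    for var, mean in recipe.means.items():
        amp = recipe.amplitudes.get(var, 0.0)
        peak = recipe.peak_hours.get(var, 0.0)
        series = (
            mean
            + amp * np.cos(2 * np.pi * (hours - peak) / 24.0)
            + rng.normal(0.0, recipe.noise_sd, size=n)
        )
        if var == "rh_pct":
            series = np.clip(series, 0.0, 100.0)
        elif var in ("co2_ppm", "light"):
            series = np.clip(series, 0.0, None)
        data[var] = np.round(series, 4)
    truth = {
        "means": dict(recipe.means),
        "peak_hours": {k: int(v) for k, v in recipe.peak_hours.items()},
        "trough_hours": {
            k: int((v + 12) % 24) for k, v in recipe.peak_hours.items()
        },
    }
    return pd.DataFrame(data), truth


def write_station_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write a log CSV with ISO-8601 timestamps, byte-stable for fixed input."""
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# truth serialization helpers


def write_truth(truth: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
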