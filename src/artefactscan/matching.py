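"""Correlation-coefficient template matching for deterioration mapping.

Given a grayscale scene ``I`` (M×N) and a smaller template ``R`` (m×n), the
correlation map ``C`` has shape ``(M-m+1, N-n+1)`` and

    C(r, s) = sum_ij (I(i+r, j+s) - mean_window) (R(i, j) - mean_R) / Z(r, s)

where ``Z`` is the product of the window and template root sums of squared
deviations, so every defined score lies in [-1, +1].  Windows with zero
variance carry a sentinel score of 0 and are flagged.  The implementation
uses FFT-based window sums; a literal double-loop transcription lives in the
test suite as an independent oracle.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import (
    DegenerateTemplateError,
    NoDetectionsError,
    UndefinedEfficiencyError,
)
from .image_io import (
    GridRef,
    PixelBox,
    annotate_boxes,
    pixel_to_gridref,
    read_image,
    to_grayscale,
    write_image,
)

__all__ = [
    "TemplatePattern",
    "CorrelationMap",
    "Detection",
    "DetectionSet",
    "EfficiencyReport",
    "correlation_map",
    "detect",
    "sweep_thresholds",
    "select_threshold",
    "efficiency",
    "run_detection",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)
#: Default fixed threshold: midpoint of the working range 0.65-0.70.
DEFAULT_THRESHOLD = 0.675
#: Default sweep bounds and step.
DEFAULT_SWEEP = (0.40, 0.95, 0.01)


@dataclass(frozen=True)
class TemplatePattern:
    """A small grayscale reference pattern to search for in a larger scene."""

    gray: np.ndarray
    template_id: str = "template"

    def __post_init__(self) -> None:
        arr = np.asarray(self.gray)
        if arr.ndim != 2:
            raise ValueError("template must be single-channel")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("template must be non-empty")
        object.__setattr__(self, "gray", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.gray.shape  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        return float(np.mean(self.gray, dtype=np.float64))

    @property
    def variance(self) -> float:
        return float(np.var(np.asarray(self.gray, dtype=np.float64)))


@dataclass
class CorrelationMap:
    """Score grid produced by sliding a template over a scene."""

    values: np.ndarray
    flat_mask: np.ndarray  # True where the scene window had zero variance
    scene_shape: tuple[int, int]
    template_shape: tuple[int, int]
    template_id: str = "template"

    def __post_init__(self) -> None:
        M, N = self.scene_shape
        m, n = self.template_shape
        expected = (M - m + 1, N - n + 1)
        if self.values.shape != expected:
            raise ValueError(
                f"correlation map shape {self.values.shape} != {expected}"
            )
        if self.flat_mask.shape != self.values.shape:
            raise ValueError("flat mask must match the score grid")


@dataclass(frozen=True)
class Detection:
    """One template hit: window anchor, bounding box and peak score."""

    anchor: tuple[int, int]
    box: PixelBox
    score: float
    template_id: str = "template"
    gridref: GridRef | None = None


@dataclass
class DetectionSet:
    detections: list[Detection]
    threshold: float
    grouping_mode: Literal["grouped", "raw"] = "grouped"

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class EfficiencyReport:
    """Sampling-efficiency summary: positives over software-detected areas."""

    n_detected: int
    n_positive: int
    n_sampled: int | None = None

    @property
    def efficiency(self) -> float:
        return 100.0 * self.n_positive / self.n_detected

    @property
    def efficiency_rounded(self) -> int:
        return int(np.floor(self.efficiency + 0.5))


def correlation_map(scene: np.ndarray, template: TemplatePattern) -> CorrelationMap:
    """Compute the normalized correlation-coefficient map of a template.

    Valid-mode only (no padding).  Raises if the template is larger than the
    scene or has zero variance.
    """
    I = np.asarray(scene, dtype=np.float64)
    if I.ndim != 2:
        raise ValueError("scene must be single-channel; convert to grayscale first")
    R = np.asarray(template.gray, dtype=np.float64)
    m, n = R.shape
    M, N = I.shape
    if m > M or n > N:
        raise ValueError(
            f"template {m}x{n} does not fit inside scene {M}x{N}"
        )
    Rc = R - R.mean()
    ss_R = float(np.sum(Rc * Rc))
    if ss_R <= 1e-12:
        raise DegenerateTemplateError(
            f"template {template.template_id!r} is constant; matching undefined"
        )

    ones = np.ones((m, n), dtype=np.float64)
    # cross-correlation with the mean-removed template; the window-mean term
    # vanishes because sum(Rc) == 0
    num = fftconvolve(I, Rc[::-1, ::-1], mode="valid")
    win_sum = fftconvolve(I, ones, mode="valid")
    win_sum2 = fftconvolve(I * I, ones, mode="valid")
    ss_win = win_sum2 - win_sum * win_sum / (m * n)
    np.clip(ss_win, 0.0, None, out=ss_win)

    # FFT round-off leaves a truly flat window's sum-of-squares at ~1e-4 for
    # 8-bit scale scenes; a single unit-step pixel contributes >= 1 - 1/(mn)
    flat = ss_win < 1e-3
    Z = np.sqrt(ss_win * ss_R)
    values = np.zeros_like(num)
    np.divide(num, Z, out=values, where=~flat)
    np.clip(values, -1.0, 1.0, out=values)
    values[flat] = 0.0
    return CorrelationMap(
        values=values,
        flat_mask=flat,
        scene_shape=(M, N),
        template_shape=(m, n),
        template_id=template.template_id,
    )


def _grouped_anchors(
    values: np.ndarray, mask: np.ndarray
) -> list[tuple[int, int, float]]:
    """Peak anchor per 8-connected component; ties go to the smallest (r, s)."""
    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n_comp == 0:
        return []
    maxima = ndimage.maximum(values, labels, index=np.arange(1, n_comp + 1))
    anchors: dict[int, tuple[int, int, float]] = {}
    for r, s in np.argwhere(mask):  # argwhere is row-major, i.e. lexicographic
        k = labels[r, s]
        if k not in anchors and values[r, s] == maxima[k - 1]:
            anchors[k] = (int(r), int(s), float(values[r, s]))
    return [anchors[k] for k in sorted(anchors)]


def detect(
    cmap: CorrelationMap,
    threshold: float,
    grouping: Literal["grouped", "raw"] = "grouped",
) -> DetectionSet:
    """Threshold the correlation map into detections.

    ``raw`` yields one detection per above-threshold pixel; ``grouped`` (the
    default) merges 8-connected above-threshold pixels into one detection
    anchored at the component's maximum score.
    """
    if not (-1.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (-1, 1]")
    m, n = cmap.template_shape
    mask = (cmap.values > threshold) & ~cmap.flat_mask
    hits: list[tuple[int, int, float]]
    if grouping == "raw":
        hits = [
            (int(r), int(s), float(cmap.values[r, s])) for r, s in np.argwhere(mask)
        ]
    elif grouping == "grouped":
        hits = _grouped_anchors(cmap.values, mask)
    else:
        raise ValueError(f"unknown grouping mode {grouping!r}")
    detections = [
        Detection(
            anchor=(r, s),
            box=PixelBox(r, s, m, n),
            score=score,
            template_id=cmap.template_id,
        )
        for r, s, score in hits
    ]
    return DetectionSet(detections=detections, threshold=threshold, grouping_mode=grouping)


def sweep_thresholds(
    cmap: CorrelationMap,
    t_lo: float = DEFAULT_SWEEP[0],
    t_hi: float = DEFAULT_SWEEP[1],
    step: float = DEFAULT_SWEEP[2],
) -> list[tuple[float, int]]:
    """Grouped-detection counts over a descending grid of thresholds."""
    if not t_lo < t_hi:
        raise ValueError("need t_lo < t_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    thresholds = np.arange(t_hi, t_lo - step / 2, -step)
    table: list[tuple[float, int]] = []
    for t in thresholds:
        mask = (cmap.values > t) & ~cmap.flat_mask
        _, n_comp = ndimage.label(mask, structure=_EIGHT_CONNECTED)
        table.append((float(round(t, 10)), int(n_comp)))
    return table


def select_threshold(
    sweep: Sequence[tuple[float, int]], jump_factor: float = 6.0
) -> float:
    """Pick the last stable threshold before the detection count jumps.

    Returns the lowest threshold ``t`` whose next-lower neighbour's count is
    at least ``jump_factor`` times ``max(count(t), 1)``.  If the counts never
    jump, returns the midpoint of the sweep range with a warning.
    """
    if not sweep:
        raise ValueError("empty sweep table")
    if jump_factor <= 1:
        raise ValueError("jump_factor must exceed 1")
    table = sorted(sweep, key=lambda tc: -tc[0])
    if all(c == 0 for _, c in table):
        raise NoDetectionsError("no detections at any threshold in the sweep")
    candidates = [
        table[i][0]
        for i in range(len(table) - 1)
        if table[i + 1][1] / max(table[i][1], 1) >= jump_factor
    ]
    if candidates:
        return min(candidates)
    midpoint = (table[0][0] + table[-1][0]) / 2.0
    warnings.warn(
        f"no count jump >= factor {jump_factor}; falling back to sweep midpoint "
        f"{midpoint:.4f}",
        stacklevel=2,
    )
    return midpoint


def efficiency(
    n_detected: int, n_positive: int, n_sampled: int | None = None
) -> EfficiencyReport:
    """Percent of software-detected areas whose sampling returned positives."""
    if n_detected < 1:
        raise UndefinedEfficiencyError("efficiency undefined without detected areas")
    if n_positive < 0:
        raise ValueError("positive count cannot be negative")
    if n_sampled is not None and n_positive > n_sampled:
        raise ValueError("cannot have more positives than sampled areas")
    return EfficiencyReport(n_detected=n_detected, n_positive=n_positive, n_sampled=n_sampled)


def run_detection(
    scene_path: str | Path,
    template_paths: Sequence[str | Path],
    threshold: float = DEFAULT_THRESHOLD,
    grouping: Literal["grouped", "raw"] = "grouped",
    grid: tuple[int, int] = (10, 10),
    out_csv: str | Path | None = None,
    overlay_path: str | Path | None = None,
) -> DetectionSet:
    """End-to-end run: grayscale, match each template, threshold, annotate.

    Detections from different templates are pooled for counting but reported
    separately (never merged).  Grid labels refer to the box centre.  Output
    files are byte-deterministic for fixed inputs.
    """
    scene = read_image(scene_path)
    gray = to_grayscale(scene)
    all_detections: list[Detection] = []
    for path in template_paths:
        tpl_img = to_grayscale(read_image(path))
        tpl = TemplatePattern(gray=tpl_img, template_id=Path(path).stem)
        cmap = correlation_map(gray.astype(np.float64), tpl)
        dset = detect(cmap, threshold, grouping)
        for d in dset.detections:
            cr, cc = d.box.centre()
            ref = pixel_to_gridref(cr, cc, gray.shape, grid)
            all_detections.append(
                Detection(d.anchor, d.box, d.score, d.template_id, gridref=ref)
            )
    all_detections.sort(key=lambda d: (d.template_id, d.anchor))
    result = DetectionSet(all_detections, threshold=threshold, grouping_mode=grouping)

    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["template_id", "anchor_row", "anchor_col", "height", "width",
                 "score", "grid_label"]
            )
            for d in result.detections:
                writer.writerow(
                    [d.template_id, d.anchor[0], d.anchor[1], d.box.height,
                     d.box.width, f"{d.score:.6f}",
                     d.gridref.label if d.gridref else ""]
                )
    if overlay_path is not None:
        overlay = annotate_boxes(scene, [d.box for d in result.detections])
        write_image(overlay_path, overlay)
    return result
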