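"""Pixel-wise relaxation-time maps, masking, ROI statistics and exports.

Applies the exponential fitters to every pixel of an
:class:`~relaxmap.dicom_io.ImageSeries`, producing a relaxation-time map, an
R^2 goodness-of-fit map and a noise mask: pixels whose fit fails or whose R^2
falls below a threshold (default 0.4) are replaced with 0 and excluded from
all statistics.  Downstream views are region-of-interest statistics
(mean +/- pixel standard deviation), single-pixel-row line profiles,
histograms, and lossless CSV / colormapped PNG / text-report exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import line as bresenham_line
from skimage.draw import polygon2mask

from .dicom_io import ImageSeries, T1_PROTOCOL
from .relaxometry import (
    batch_fit,
    fit_biexponential,
    normalize_signal,
    smooth_series,
)

DEFAULT_R2_THRESHOLD = 0.4


class RoiError(ValueError):
    """Raised for regions that miss the image or contain no usable pixels."""


@dataclass
class RoiSelection:
    """A pixel-coordinate region of interest.

    ``kind`` is one of ``full``, ``rectangle``, ``circle``, ``polygon``.
    Coordinates are 0-based (row, col); rectangle bounds are half-open.
    """

    kind: str = "full"
    # rectangle: (row0, col0, row1, col1), half-open
    bounds: tuple[int, int, int, int] | None = None
    # circle: (row, col) centre and radius in pixels
    center: tuple[float, float] | None = None
    radius: float | None = None
    # polygon: (row, col) vertices
    vertices: Sequence[tuple[float, float]] | None = None
    # mask: explicit boolean membership grid
    grid: np.ndarray | None = None

    @classmethod
    def full(cls) -> "RoiSelection":
        return cls(kind="full")

    @classmethod
    def from_mask(cls, grid: np.ndarray) -> "RoiSelection":
        """Explicit boolean-grid ROI (e.g. a phantom label region)."""
        return cls(kind="mask", grid=np.asarray(grid, dtype=bool))

    @classmethod
    def rectangle(cls, row0: int, col0: int, row1: int, col1: int) -> "RoiSelection":
        return cls(kind="rectangle", bounds=(row0, col0, row1, col1))

    @classmethod
    def circle(cls, row: float, col: float, radius: float) -> "RoiSelection":
        return cls(kind="circle", center=(row, col), radius=radius)

    @classmethod
    def polygon(cls, vertices: Sequence[tuple[float, float]]) -> "RoiSelection":
        return cls(kind="polygon", vertices=list(vertices))

    @classmethod
    def parse(cls, text: str) -> "RoiSelection":
        """Parse a CLI/config ROI spec.

        ``full`` | ``rect:r0,c0,r1,c1`` | ``circle:row,col,radius`` |
        ``polygon:r0,c0;r1,c1;...``
        """
        text = text.strip()
        if text == "full":
            return cls.full()
        kind, _, rest = text.partition(":")
        if kind == "rect":
            r0, c0, r1, c1 = (int(v) for v in rest.split(","))
            return cls.rectangle(r0, c0, r1, c1)
        if kind == "circle":
            row, col, rad = (float(v) for v in rest.split(","))
            return cls.circle(row, col, rad)
        if kind == "polygon":
            verts = [tuple(float(v) for v in pair.split(","))
                     for pair in rest.split(";")]
            return cls.polygon(verts)
        raise RoiError(f"unrecognised ROI spec {text!r}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership grid; raises :class:`RoiError` when the region
        misses the image entirely."""
        rows, cols = shape
        if self.kind == "full":
            return np.ones(shape, dtype=bool)
        if self.kind == "rectangle":
            r0, c0, r1, c1 = self.bounds
            if r1 <= r0 or c1 <= c0:
                raise RoiError("empty rectangle")
            m = np.zeros(shape, dtype=bool)
            m[max(r0, 0):min(r1, rows), max(c0, 0):min(c1, cols)] = True
        elif self.kind == "circle":
            rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
            m = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 \
                <= self.radius ** 2
        elif self.kind == "polygon":
            m = polygon2mask(shape, np.asarray(self.vertices))
        elif self.kind == "mask":
            if self.grid.shape != shape:
                raise RoiError("mask ROI shape does not match the image")
            m = self.grid
        else:
            raise RoiError(f"unknown ROI kind {self.kind!r}")
        if not m.any():
            raise RoiError("ROI does not intersect the image")
        return m


@dataclass
class RelaxationMap:
    """Per-pixel relaxation times with their R^2 map and noise mask.

    ``time_ms`` is exactly 0 wherever ``mask`` is false (failed fits, R^2
    below ``r2_threshold``, or pixels outside the fitted ROI);
    ``r_squared`` is NaN outside the fitted region.  ``provenance`` records
    the acquisition schedule and fit options.
    """

    time_ms: np.ndarray
    r_squared: np.ndarray
    mask: np.ndarray
    mode: str
    r2_threshold: float
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time_ms.shape == self.r_squared.shape == self.mask.shape):
            raise ValueError("map grids must share one shape")
        if np.any((self.time_ms != 0) != self.mask):
            raise ValueError("time_ms must be non-zero exactly where mask is true")


def fit_map(
    series: ImageSeries,
    roi: RoiSelection | None = None,
    model: str = "mono",
    smoothing: str = "none",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    normalize: bool = True,
) -> RelaxationMap:
    """Fit every ROI pixel's intensity-time sequence and mask poor fits.

    The mode-appropriate fitter (saturation-recovery for a TR-varying series,
    exponential decay for a TE-varying one) runs on each pixel's sequence
    after optional smoothing and per-pixel normalisation.  Pixels outside the
    ROI, with invalid fits, or with R^2 below ``r2_threshold`` are set to 0
    and masked out.  Deterministic for fixed inputs.
    """
    series.validate()
    if model not in ("mono", "biexp"):
        raise ValueError(f"unknown model {model!r}")
    roi = roi or RoiSelection.full()
    roi_mask = roi.mask(series.shape)

    working = smooth_series(series, smoothing) if smoothing != "none" else series
    stack = working.stack()
    times = working.varied_times_ms

    time_grid = np.zeros(series.shape)
    r2_grid = np.full(series.shape, np.nan)
    keep = np.zeros(series.shape, dtype=bool)

    is_t1 = series.mode == T1_PROTOCOL
    rows, cols = np.nonzero(roi_mask)
    if model == "mono":
        # vectorised variable-projection solver; same objective as the
        # per-pixel fitters but orders of magnitude faster over a grid
        pixel_series = stack[:, rows, cols].T
        out = batch_fit(times, pixel_series, mode="T1" if is_t1 else "T2",
                        normalize=normalize)
        r2_grid[rows, cols] = out["r_squared"]
        kept = out["valid"] & (out["r_squared"] >= r2_threshold)
        time_grid[rows, cols] = np.where(kept, out["time_ms"], 0.0)
        keep[rows, cols] = kept
    else:
        for r, c in zip(rows, cols):
            y = stack[:, r, c]
            try:
                if normalize:
                    y = normalize_signal(y)
                fit = fit_biexponential(times, y, mode="T1" if is_t1 else "T2")
            except ValueError:
                continue  # degenerate pixel: stays masked at 0
            r2_grid[r, c] = fit.r_squared
            if fit.valid and fit.r_squared >= r2_threshold:
                time_grid[r, c] = fit.time_ms
                keep[r, c] = True

    provenance = {
        "mode": series.mode,
        "varied_times_ms": [float(t) for t in series.varied_times_ms],
        "fixed_parameter_ms": float(series.fixed_parameter_ms),
        "model": model,
        "smoothing": smoothing,
        "r2_threshold": float(r2_threshold),
        "normalize": bool(normalize),
        "roi": roi.kind,
    }
    return RelaxationMap(
        time_ms=time_grid, r_squared=r2_grid, mask=keep, mode=series.mode,
        r2_threshold=r2_threshold, pixel_spacing_mm=series.pixel_spacing_mm,
        provenance=provenance,
    )


def roi_stats(rmap: RelaxationMap, roi: RoiSelection | None = None
              ) -> tuple[float, float, int]:
    """Mean, pixel standard deviation and count over kept pixels of a region.

    The SD is the population convention (divide by n).  Raises
    :class:`RoiError` when the region holds no unmasked pixel.
    """
    roi = roi or RoiSelection.full()
    kept = roi.mask(rmap.time_ms.shape) & rmap.mask
    n = int(kept.sum())
    if n == 0:
        raise RoiError("empty ROI after masking")
    values = rmap.time_ms[kept]
    return float(values.mean()), float(values.std(ddof=0)), n


def compare_rois(map_a: RelaxationMap, map_b: RelaxationMap,
                 roi: RoiSelection | None = None) -> dict:
    """Welch two-sample t-test between the kept pixel populations of two maps."""
    from scipy import stats

    roi = roi or RoiSelection.full()
    vals = []
    for m in (map_a, map_b):
        kept = roi.mask(m.time_ms.shape) & m.mask
        if not kept.any():
            raise RoiError("empty ROI after masking")
        vals.append(m.time_ms[kept])
    t, p = stats.ttest_ind(vals[0], vals[1], equal_var=False)
    return {"t": float(t), "p": float(p), "n_a": len(vals[0]), "n_b": len(vals[1])}


def line_profile(rmap: RelaxationMap, start: tuple[int, int],
                 end: tuple[int, int]) -> np.ndarray:
    """Relaxation times along the rasterised segment from start to end.

    Sampling follows the Bresenham line (one row of pixels); masked pixels
    contribute their stored 0.  Returns an (n, 2) array of
    (distance from start in mm, time in ms).
    """
    rows, cols = rmap.time_ms.shape
    for r, c in (start, end):
        if not (0 <= r < rows and 0 <= c < cols):
            raise RoiError("profile endpoint outside the image")
    if tuple(start) == tuple(end):
        raise RoiError("zero-length profile segment")
    rr, cc = bresenham_line(int(start[0]), int(start[1]), int(end[0]), int(end[1]))
    dr = (rr - start[0]) * rmap.pixel_spacing_mm[0]
    dc = (cc - start[1]) * rmap.pixel_spacing_mm[1]
    dist = np.hypot(dr, dc)
    return np.column_stack([dist, rmap.time_ms[rr, cc]])


def histogram(rmap: RelaxationMap, roi: RoiSelection | None = None,
              bins: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of kept relaxation times in a region (masked zeros excluded).

    Returns (bin_edges_ms, counts); counts sum to the region's kept-pixel
    count.
    """
    if bins < 1:
        raise ValueError("bins must be at least 1")
    roi = roi or RoiSelection.full()
    kept = roi.mask(rmap.time_ms.shape) & rmap.mask
    if not kept.any():
        raise RoiError("empty ROI after masking")
    counts, edges = np.histogram(rmap.time_ms[kept], bins=bins)
    return edges, counts


def load_map_csv(path: str | Path) -> np.ndarray:
    """Reload a CSV grid written by :func:`export_map`."""
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def export_map(rmap: RelaxationMap, out_path: str | Path, format: str = "csv",
               roi: RoiSelection | None = None, colormap: str = "viridis") -> Path:
    """Export a relaxation map.

    ``csv``: the time grid at full float precision (lossless; masked pixels
    are 0).  ``png``: colormapped image with a colorbar; masked pixels are
    drawn in black.  ``report``: plain-text provenance (schedule, options,
    R^2 threshold) plus ROI statistics.
    """
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        np.savetxt(out, rmap.time_ms, delimiter=",", fmt="%.17g")
        return out
    if format == "png":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        shown = np.ma.masked_where(~rmap.mask, rmap.time_ms)
        cmap = matplotlib.colormaps[colormap].copy()
        cmap.set_bad("black")  # reserved colour for masked pixels
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(shown, cmap=cmap, interpolation="nearest")
        fig.colorbar(im, ax=ax, label=f"{rmap.mode} [ms]")
        ax.set_title(f"{rmap.mode} map (R^2 >= {rmap.r2_threshold:g})")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        return out
    if format == "report":
        mean, sd, n = roi_stats(rmap, roi)
        lines = [
            f"relaxmap {rmap.mode} map report",
            f"mode: {rmap.mode}",
            f"r2_threshold: {rmap.r2_threshold:g}",
            f"kept_pixels: {int(rmap.mask.sum())}",
            f"roi_mean_ms: {mean:.6g}",
            f"roi_sd_ms: {sd:.6g}  (population SD, divide by n)",
            f"roi_n_pixels: {n}",
        ]
        for key, value in rmap.provenance.items():
            lines.append(f"provenance.{key}: {value}")
        out.write_text("\n".join(lines) + "\n")
        return out
    raise ValueError(f"unknown export format {format!r}")
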