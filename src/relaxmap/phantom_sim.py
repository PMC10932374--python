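"""Digital phantoms and spin-echo signal simulation.

Ground-truth parameter maps — proton density PD, longitudinal relaxation time
T1 and transverse relaxation time T2 per pixel — are built for two geometries:

* a capillary resolution phantom: a water-filled test tube (inner diameter
  13.8 mm) holding 16 thin-walled capillaries (2.3 mm outer diameter, 0.4 mm
  wall), imaged at FOV 5 cm on a 512 x 512 matrix;
* a hollow-fiber bioreactor cross-section: a cell mass with short T1/T2
  around porous fibers, surrounded by a culture-medium annulus with long
  T1/T2.

From such maps, :func:`simulate_series` renders a saturation-recovery
(variable TR) or multi-echo (variable TE) magnitude series with the spin-echo
signal model

    IS = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)

plus Rician noise (Gaussian noise on two quadrature channels followed by the
modulus), which is Rayleigh-distributed where PD = 0.  Output is an
:class:`~relaxmap.dicom_io.ImageSeries` ready for DICOM export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dicom_io import AcquisitionFrame, ImageSeries, T1_PROTOCOL, T2_PROTOCOL

# region label codes
BACKGROUND = 0
TUBE_WATER = 1
CAPILLARY_WALL = 2
CAPILLARY_LUMEN = 3
CELL_REGION = 4
MEDIUM = 5

LABEL_NAMES = {
    "background": BACKGROUND,
    "tube_water": TUBE_WATER,
    "capillary_wall": CAPILLARY_WALL,
    "capillary_lumen": CAPILLARY_LUMEN,
    "cell_region": CELL_REGION,
    "medium": MEDIUM,
}

# acquisition schedules: TR sweep at short fixed TE for T1, TE sweep at long
# fixed TR for T2
T1_TR_SCHEDULE_MS = (500.0, 700.0, 1000.0, 1500.0, 2000.0, 3000.0,
                     5000.0, 10000.0, 15000.0)
T1_FIXED_TE_MS = 3.0
T2_TE_SCHEDULE_MS = (10.0, 20.0, 26.2, 42.0, 68.0, 85.0, 102.0, 130.0,
                     160.0, 200.0)
T2_FIXED_TR_MS = 10000.0


class GeometryError(ValueError):
    """Raised when a phantom geometry cannot be realised."""


def t1_schedule(te_ms: float = T1_FIXED_TE_MS) -> list[tuple[float, float]]:
    """The 9-point saturation-recovery (TR, TE) schedule."""
    return [(tr, te_ms) for tr in T1_TR_SCHEDULE_MS]


def t2_schedule(tr_ms: float = T2_FIXED_TR_MS) -> list[tuple[float, float]]:
    """The 10-point multi-echo (TR, TE) schedule."""
    return [(tr_ms, te) for te in T2_TE_SCHEDULE_MS]


def signal_model(pd, t1_ms, t2_ms, tr_ms, te_ms):
    """Noiseless spin-echo magnitude signal.

    ``PD * (1 - exp(-TR/T1)) * exp(-TE/T2)``.  Strictly increasing in TR,
    strictly decreasing in TE, and tending to PD as TR grows at TE = 0.
    Accepts scalars or broadcastable arrays; times in milliseconds.
    """
    pd = np.asarray(pd, dtype=np.float64)
    t1 = np.asarray(t1_ms, dtype=np.float64)
    t2 = np.asarray(t2_ms, dtype=np.float64)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be strictly positive")
    if np.any(pd < 0):
        raise ValueError("PD must be non-negative")
    if np.any(np.asarray(tr_ms) <= 0) or np.any(np.asarray(te_ms) < 0):
        raise ValueError("TR must be positive and TE non-negative")
    out = pd * (1.0 - np.exp(-np.divide(tr_ms, t1))) * np.exp(-np.divide(te_ms, t2))
    return out if out.ndim else float(out)


# (PD, T1 ms, T2 ms) per compartment.  Demineralised water at 1.5 T has long
# relaxation times; capillary walls are plastic and give no signal.
_WATER = (1.0, 2900.0, 1800.0)
DEFAULT_CAPILLARY_PARAMS = {
    "background": (0.0, 1.0, 1.0),
    "tube_water": _WATER,
    "capillary_wall": (0.0, 1.0, 1.0),
    "capillary_lumen": _WATER,
}


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a circular phantom.

    Defaults reproduce the capillary resolution phantom: FOV 50 mm on a
    512 x 512 matrix (0.09766 mm/pixel), a 13.8 mm inner-diameter test tube
    holding 16 capillaries of 2.3 mm outer diameter and 0.4 mm wall.

    ``cell_region_diameter_mm`` switches the tube interior to a concentric
    bioreactor layout: a cell region of that diameter surrounded by a medium
    annulus, with the "capillaries" acting as hollow fibers.
    """

    fov_mm: float = 50.0
    matrix: int = 512
    tube_inner_diameter_mm: float = 13.8
    capillary_count: int = 16
    capillary_outer_diameter_mm: float = 2.3
    capillary_wall_mm: float = 0.4
    compartment_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CAPILLARY_PARAMS)
    )
    cell_region_diameter_mm: float | None = None
    placement_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise GeometryError("fov_mm must be positive")
        if self.matrix < 16:
            raise GeometryError("matrix must be at least 16")
        if self.capillary_count < 0:
            raise GeometryError("capillary_count must be non-negative")
        if self.capillary_count > 0:
            if self.capillary_wall_mm * 2 >= self.capillary_outer_diameter_mm:
                raise GeometryError("capillary wall thicker than its radius")
        for name, (pd, t1, t2) in self.compartment_params.items():
            if pd < 0 or t1 <= 0 or t2 <= 0:
                raise GeometryError(f"invalid (PD, T1, T2) for {name!r}")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.matrix

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "compartment_params" in data:
            data["compartment_params"] = {
                k: tuple(v) for k, v in data["compartment_params"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "fov_mm": self.fov_mm,
            "matrix": self.matrix,
            "tube_inner_diameter_mm": self.tube_inner_diameter_mm,
            "capillary_count": self.capillary_count,
            "capillary_outer_diameter_mm": self.capillary_outer_diameter_mm,
            "capillary_wall_mm": self.capillary_wall_mm,
            "compartment_params": {
                k: list(v) for k, v in self.compartment_params.items()
            },
            "cell_region_diameter_mm": self.cell_region_diameter_mm,
            "placement_jitter_mm": self.placement_jitter_mm,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def bioreactor_spec(
    cell_t1_ms: float = 1100.0,
    cell_t2_ms: float = 171.0,
    matrix: int = 128,
    fov_mm: float = 20.0,
    fiber_count: int = 5,
    seed: int = 0,
) -> PhantomSpec:
    """Concentric bioreactor cross-section preset.

    A cell region (default T1 = 1100 ms, T2 = 171 ms — an early 3D MCF-7
    culture; late cultures drop to roughly 673/128 ms) sits inside a
    culture-medium annulus with much longer relaxation times, pierced by
    hollow fibers (1.3 mm outer diameter, 0.3 mm porous wall).
    """
    params = {
        "background": (0.0, 1.0, 1.0),
        "medium": (1.0, 2500.0, 900.0),
        "cell_region": (0.9, cell_t1_ms, cell_t2_ms),
        "capillary_wall": (0.0, 1.0, 1.0),
        "capillary_lumen": (1.0, 2500.0, 900.0),
    }
    return PhantomSpec(
        fov_mm=fov_mm,
        matrix=matrix,
        tube_inner_diameter_mm=10.0,
        capillary_count=fiber_count,
        capillary_outer_diameter_mm=1.3,
        capillary_wall_mm=0.3,
        compartment_params=params,
        cell_region_diameter_mm=7.0,
        seed=seed,
    )


def _ring_capacity(ring_r: float, circle_r: float, gap: float) -> int:
    """How many non-overlapping circles of radius ``circle_r`` fit on a ring."""
    if ring_r <= 0:
        return 0
    need = 2 * circle_r + gap
    if need >= 2 * ring_r:
        return 1
    return int(math.pi // math.asin(need / (2 * ring_r)))


def _ring_layout(
    count: int, container_r: float, circle_r: float,
    gap: float, rng: np.random.Generator, jitter: float,
) -> list[tuple[float, float]]:
    """Deterministic concentric-ring packing of ``count`` circles.

    Rings are filled from the outside in; a final single circle may sit at
    the centre.  Raises :class:`GeometryError` when the circles cannot fit.
    """
    if count == 0:
        return []
    if circle_r + gap > container_r:
        raise GeometryError("capillary larger than its container")
    centers: list[tuple[float, float]] = []
    ring_r = container_r - circle_r - gap
    ring_idx = 0
    remaining = count
    while remaining > 0 and ring_r > circle_r:
        cap = _ring_capacity(ring_r, circle_r, gap)
        n = min(cap, remaining)
        offset = ring_idx * math.pi / 7.0  # stagger successive rings
        for k in range(n):
            ang = offset + 2 * math.pi * k / n
            x, y = ring_r * math.cos(ang), ring_r * math.sin(ang)
            if jitter > 0:
                x += rng.uniform(-jitter, jitter)
                y += rng.uniform(-jitter, jitter)
            centers.append((x, y))
        remaining -= n
        ring_r -= 2 * circle_r + gap
        ring_idx += 1
    if remaining == 1 and not any(math.hypot(*c) < 2 * circle_r + gap
                                  for c in centers):
        centers.append((0.0, 0.0))
        remaining = 0
    if remaining > 0:
        raise GeometryError(
            f"cannot pack {count} capillaries of radius {circle_r} mm "
            f"inside radius {container_r} mm"
        )
    return centers


@dataclass
class ParameterMaps:
    """Per-pixel ground truth: PD, T1, T2 and a region-label grid."""

    pd: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    labels: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        shapes = {self.pd.shape, self.t1_ms.shape, self.t2_ms.shape,
                  self.labels.shape}
        if len(shapes) != 1:
            raise GeometryError("parameter grids must share one shape")
        signal = self.pd > 0
        if np.any(self.t1_ms[signal] <= 0) or np.any(self.t2_ms[signal] <= 0):
            raise GeometryError("T1 and T2 must be positive wherever PD > 0")

    def export_csv(self, prefix: str | Path) -> list[Path]:
        """Write pd/t1/t2/labels grids as ``<prefix>_<name>.csv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        written = []
        for name, grid, fmt in (("pd", self.pd, "%.17g"),
                                ("t1_ms", self.t1_ms, "%.17g"),
                                ("t2_ms", self.t2_ms, "%.17g"),
                                ("labels", self.labels, "%d")):
            path = prefix.parent / f"{prefix.name}_{name}.csv"
            np.savetxt(path, grid, delimiter=",", fmt=fmt)
            written.append(path)
        return written


def build_phantom(spec: PhantomSpec) -> ParameterMaps:
    """Rasterise a :class:`PhantomSpec` into ground-truth parameter maps.

    Region membership is decided at pixel centres (no partial-volume
    averaging), so label counts and component counts are exact.  Deterministic
    for a fixed ``spec.seed``.
    """
    n = spec.matrix
    h = spec.pixel_spacing_mm
    # pixel centres, phantom centred on the grid
    coords = (np.arange(n) + 0.5) * h - spec.fov_mm / 2.0
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(xx, yy)

    tube_r = spec.tube_inner_diameter_mm / 2.0
    labels = np.full((n, n), BACKGROUND, dtype=np.int32)
    if spec.cell_region_diameter_mm is None:
        labels[rr <= tube_r] = TUBE_WATER
        container_r = tube_r
    else:
        cell_r = spec.cell_region_diameter_mm / 2.0
        if cell_r >= tube_r:
            raise GeometryError("cell region must fit inside the tube")
        labels[rr <= tube_r] = MEDIUM
        labels[rr <= cell_r] = CELL_REGION
        container_r = cell_r

    rng = np.random.default_rng(spec.seed)
    outer_r = spec.capillary_outer_diameter_mm / 2.0
    lumen_r = outer_r - spec.capillary_wall_mm
    centers = _ring_layout(
        spec.capillary_count, container_r, outer_r,
        gap=0.05, rng=rng, jitter=spec.placement_jitter_mm,
    )
    for cx, cy in centers:
        d = np.hypot(xx - cx, yy - cy)
        labels[d <= outer_r] = CAPILLARY_WALL
        labels[d <= lumen_r] = CAPILLARY_LUMEN

    pd = np.zeros((n, n))
    t1 = np.ones((n, n))
    t2 = np.ones((n, n))
    for name, (p, a, b) in spec.compartment_params.items():
        mask = labels == LABEL_NAMES[name]
        pd[mask], t1[mask], t2[mask] = p, a, b

    return ParameterMaps(pd=pd, t1_ms=t1, t2_ms=t2, labels=labels,
                         pixel_spacing_mm=h)


def simulate_series(
    maps: ParameterMaps,
    schedule: Sequence[tuple[float, float]],
    noise_sigma: float = 0.0,
    seed: int = 0,
    intensity_scale: float | None = 40000.0,
    slice_thickness_mm: float = 1.0,
) -> ImageSeries:
    """Render an image series from ground-truth maps.

    ``schedule`` is a list of (TR ms, TE ms) pairs varying exactly one of the
    two.  ``noise_sigma`` is the per-channel Gaussian noise level in PD units;
    the magnitude operation makes the result Rician (Rayleigh where PD = 0).
    With ``intensity_scale`` set (the default), signals are scaled and rounded
    to integer counts in the 16-bit range, as a scanner stores them, which
    makes DICOM round-trips bit-exact; pass ``None`` for raw floats.
    Reproducible for fixed ``seed``.
    """
    if len(schedule) < 3:
        raise ValueError("schedule needs at least 3 timing points")
    trs = [tr for tr, _ in schedule]
    tes = [te for _, te in schedule]
    tr_varies = len(set(trs)) > 1
    te_varies = len(set(tes)) > 1
    if tr_varies and te_varies:
        raise ValueError("ambiguous protocol: schedule varies both TR and TE")
    if not tr_varies and not te_varies:
        raise ValueError("degenerate schedule: neither TR nor TE varies")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")

    rng = np.random.default_rng(seed)
    frames = []
    for tr, te in schedule:
        clean = signal_model(maps.pd, maps.t1_ms, maps.t2_ms, tr, te)
        if noise_sigma > 0:
            re = clean + rng.normal(0.0, noise_sigma, clean.shape)
            im = rng.normal(0.0, noise_sigma, clean.shape)
            img = np.hypot(re, im)
        else:
            img = clean
        if intensity_scale is not None:
            img = np.clip(np.round(img * intensity_scale), 0, 2**16 - 1)
        frames.append(AcquisitionFrame(
            pixels=img, tr_ms=tr, te_ms=te,
            pixel_spacing_mm=(maps.pixel_spacing_mm, maps.pixel_spacing_mm),
            slice_thickness_mm=slice_thickness_mm,
            frame_id=f"synthetic TR={tr:g} TE={te:g}",
        ))

    mode = T1_PROTOCOL if tr_varies else T2_PROTOCOL
    order = np.argsort(trs if tr_varies else tes)
    frames = [frames[i] for i in order]
    fixed = tes[0] if tr_varies else trs[0]
    return ImageSeries(frames=frames, mode=mode, fixed_parameter_ms=fixed)
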