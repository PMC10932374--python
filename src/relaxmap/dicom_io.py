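"""Reading and writing of spin-echo DICOM series.

A relaxometry acquisition is a stack of 2D magnitude images that differ in a
single timing parameter: repetition time TR for a T1 (saturation-recovery)
protocol, echo time TE for a T2 (multi-echo) protocol.  This module discovers
such series on disk (through a DICOMDIR index when present, by recursive scan
otherwise), loads them into :class:`ImageSeries` objects with frames sorted on
the varied parameter, and writes standard-conformant single-frame DICOM files
so that simulated data can round-trip through the same reader.

Stored pixels are 16-bit unsigned with RescaleSlope/RescaleIntercept applied
on read, matching clinical magnitude exports.  Series whose pixel data are
non-negative integers below 2**16 round-trip bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

logger = logging.getLogger(__name__)

T1_PROTOCOL = "T1"
T2_PROTOCOL = "T2"

_MAX_STORED = 2**16 - 1


class DicomIOError(ValueError):
    """Raised for unreadable, inconsistent or ambiguous DICOM input."""


@dataclass
class AcquisitionFrame:
    """One 2D magnitude image tagged with its acquisition timing.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities in arbitrary scanner units
        (rescale slope/intercept already applied).
    tr_ms, te_ms
        Repetition and echo time in milliseconds.
    pixel_spacing_mm
        Physical (row, column) spacing of the grid.
    slice_thickness_mm
        Slice thickness in millimetres.
    frame_id
        Stable identifier: source file path or a synthetic tag.
    """

    pixels: np.ndarray
    tr_ms: float
    te_ms: float
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_thickness_mm: float = 1.0
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DicomIOError("frame pixels must be a 2D grid")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise DicomIOError("frame pixels must be finite and non-negative")
        if not self.tr_ms > 0:
            raise DicomIOError("tr_ms must be positive")
        # TE = 0 is allowed as the idealised TE -> 0 limit of a T1 protocol
        if self.te_ms < 0:
            raise DicomIOError("te_ms must be non-negative")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise DicomIOError("pixel spacing components must be positive")


@dataclass
class ImageSeries:
    """Ordered stack of same-shape frames varying TR (T1 mode) or TE (T2 mode).

    ``mode`` is :data:`T1_PROTOCOL` when TR varies at fixed TE and
    :data:`T2_PROTOCOL` when TE varies at fixed TR.  ``fixed_parameter_ms``
    holds the constant TE (T1 mode) or TR (T2 mode).  At least three frames
    are required so a three-parameter exponential can be fitted.
    """

    frames: list[AcquisitionFrame]
    mode: str
    fixed_parameter_ms: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in (T1_PROTOCOL, T2_PROTOCOL):
            raise DicomIOError(f"unknown protocol mode {self.mode!r}")
        if len(self.frames) < 3:
            raise DicomIOError(
                "at least 3 frames are required for exponential fitting"
            )
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) != 1:
            raise DicomIOError("inconsistent series geometry")
        spacings = {f.pixel_spacing_mm for f in self.frames}
        if len(spacings) != 1:
            raise DicomIOError("inconsistent pixel spacing across frames")
        varied = self.varied_times_ms
        if np.any(np.diff(varied) <= 0):
            raise DicomIOError("varied parameter must be strictly increasing")
        fixed = [f.te_ms for f in self.frames] if self.mode == T1_PROTOCOL \
            else [f.tr_ms for f in self.frames]
        if len(set(fixed)) != 1:
            raise DicomIOError("fixed parameter varies across frames")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].pixels.shape

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return self.frames[0].pixel_spacing_mm

    @property
    def varied_times_ms(self) -> np.ndarray:
        """TR values (T1 mode) or TE values (T2 mode), in frame order."""
        if self.mode == T1_PROTOCOL:
            return np.array([f.tr_ms for f in self.frames])
        return np.array([f.te_ms for f in self.frames])

    def stack(self) -> np.ndarray:
        """Pixel data as an (n_frames, rows, cols) array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class CatalogEntry:
    path: Path
    tr_ms: float | None
    te_ms: float | None
    rows: int
    cols: int
    series_uid: str


@dataclass
class SeriesCatalog:
    """Grouping of DICOM files into candidate series.

    Groups are keyed by SeriesInstanceUID (or a geometry-based fallback key)
    and hold catalog entries recording path, TR, TE and grid size.
    """

    root: Path
    groups: dict[str, list[CatalogEntry]] = field(default_factory=dict)
    skipped: list[Path] = field(default_factory=list)

    def keys(self) -> list[str]:
        return sorted(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def to_frame(self):
        """Catalog as a pandas DataFrame (path, TR ms, TE ms, rows, cols)."""
        import pandas as pd

        rows = [
            {
                "series": key,
                "path": str(e.path),
                "tr_ms": e.tr_ms,
                "te_ms": e.te_ms,
                "rows": e.rows,
                "cols": e.cols,
            }
            for key, entries in sorted(self.groups.items())
            for e in entries
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _dicomdir_paths(dicomdir: Path) -> list[Path]:
    """File paths referenced by a DICOMDIR index."""
    from pydicom.fileset import FileSet

    fs = FileSet(pydicom.dcmread(dicomdir))
    return [Path(instance.path) for instance in fs]


def _candidate_files(root: Path) -> list[Path]:
    dicomdir = next(
        (p for p in root.rglob("*") if p.name.upper() == "DICOMDIR"), None
    )
    if dicomdir is not None:
        try:
            paths = _dicomdir_paths(dicomdir)
            if paths:
                return sorted(paths)
        except Exception:  # fall back to a plain scan on a broken index
            logger.warning("unreadable DICOMDIR %s; falling back to scan", dicomdir)
    return sorted(p for p in root.rglob("*") if p.is_file())


def _tag_float(ds, name: str) -> float | None:
    value = getattr(ds, name, None)
    if value in (None, ""):
        return None
    return float(value)


def catalog_series(root_path: str | Path) -> SeriesCatalog:
    """Catalog the DICOM files under ``root_path`` into candidate series.

    A DICOMDIR index is used when present; otherwise the directory is scanned
    recursively.  Files that are not readable DICOM, or that lack pixel data,
    are logged and skipped.  Files are grouped by SeriesInstanceUID, falling
    back to a grid-geometry key when the UID is missing.

    Raises
    ------
    DicomIOError
        If the directory contains no readable DICOM image at all
        ("no DICOM input found").
    """
    root = Path(root_path)
    if not root.is_dir():
        raise DicomIOError(f"no DICOM input found: {root} is not a directory")

    catalog = SeriesCatalog(root=root)
    for path in _candidate_files(root):
        try:
            ds = pydicom.dcmread(path, force=False)
        except Exception:
            logger.info("skipping non-DICOM file %s", path)
            catalog.skipped.append(path)
            continue
        if "PixelData" not in ds:
            logger.info("skipping DICOM file without pixel data %s", path)
            catalog.skipped.append(path)
            continue
        uid = str(getattr(ds, "SeriesInstanceUID", "") or "")
        entry = CatalogEntry(
            path=path,
            tr_ms=_tag_float(ds, "RepetitionTime"),
            te_ms=_tag_float(ds, "EchoTime"),
            rows=int(ds.Rows),
            cols=int(ds.Columns),
            series_uid=uid,
        )
        key = uid if uid else f"geometry:{entry.rows}x{entry.cols}"
        catalog.groups.setdefault(key, []).append(entry)

    if not catalog.groups:
        raise DicomIOError(f"no DICOM input found under {root}")
    return catalog


def _frame_from_dataset(ds, path: Path) -> AcquisitionFrame:
    tr = _tag_float(ds, "RepetitionTime")
    te = _tag_float(ds, "EchoTime")
    if tr is None or te is None:
        raise DicomIOError(f"missing timing metadata (TR/TE) in {path}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(ds, "SliceThickness", 1.0))
    return AcquisitionFrame(
        pixels=np.clip(pixels, 0.0, None),
        tr_ms=tr,
        te_ms=te,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        slice_thickness_mm=thickness,
        frame_id=str(path),
    )


def _average_duplicates(frames: list[AcquisitionFrame]) -> list[AcquisitionFrame]:
    """Average frames sharing identical (TR, TE); the fit expects one
    intensity per timing point."""
    by_time: dict[tuple[float, float], list[AcquisitionFrame]] = {}
    for f in frames:
        by_time.setdefault((f.tr_ms, f.te_ms), []).append(f)
    out = []
    for (tr, te), group in by_time.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            logger.info("averaging %d duplicate frames at TR=%g TE=%g",
                        len(group), tr, te)
            mean = np.mean([g.pixels for g in group], axis=0)
            out.append(AcquisitionFrame(
                pixels=mean, tr_ms=tr, te_ms=te,
                pixel_spacing_mm=group[0].pixel_spacing_mm,
                slice_thickness_mm=group[0].slice_thickness_mm,
                frame_id=group[0].frame_id + "+avg",
            ))
    return out


def load_series(catalog: SeriesCatalog, selector: str | None = None) -> ImageSeries:
    """Load one cataloged series as an :class:`ImageSeries`.

    ``selector`` is a group key from :meth:`SeriesCatalog.keys`; it may be
    omitted when the catalog holds a single group.  Frames are sorted
    ascending on the varied parameter and the protocol mode is inferred from
    which timing tag varies.
    """
    if selector is None:
        if len(catalog.groups) != 1:
            raise DicomIOError(
                f"catalog holds {len(catalog.groups)} series; a selector is required"
            )
        selector = next(iter(catalog.groups))
    if selector not in catalog.groups:
        raise DicomIOError(f"series {selector!r} not in catalog")

    frames = []
    for entry in catalog.groups[selector]:
        ds = pydicom.dcmread(entry.path)
        frames.append(_frame_from_dataset(ds, entry.path))

    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise DicomIOError("inconsistent series geometry")
    frames = _average_duplicates(frames)
    if len(frames) < 3:
        raise DicomIOError(
            f"series has {len(frames)} distinct timing points; at least 3 required"
        )

    tr_varies = len({f.tr_ms for f in frames}) > 1
    te_varies = len({f.te_ms for f in frames}) > 1
    if tr_varies and te_varies:
        raise DicomIOError("ambiguous protocol: both TR and TE vary")
    if not tr_varies and not te_varies:
        raise DicomIOError("degenerate series: neither TR nor TE varies")

    if tr_varies:
        frames.sort(key=lambda f: f.tr_ms)
        return ImageSeries(frames, T1_PROTOCOL, fixed_parameter_ms=frames[0].te_ms)
    frames.sort(key=lambda f: f.te_ms)
    return ImageSeries(frames, T2_PROTOCOL, fixed_parameter_ms=frames[0].tr_ms)


def _quantize(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map non-negative floats onto uint16 storage with a rescale slope.

    Integer-valued input within the 16-bit range is stored with slope 1
    (lossless); anything else is scaled so the maximum maps to 65535.
    """
    if np.all(pixels == np.round(pixels)) and pixels.max(initial=0) <= _MAX_STORED:
        return pixels.astype(np.uint16), 1.0, 0.0
    peak = float(pixels.max(initial=0))
    slope = peak / _MAX_STORED if peak > 0 else 1.0
    stored = np.round(pixels / slope).astype(np.uint16)
    return stored, slope, 0.0


def write_series(
    series: ImageSeries,
    out_dir: str | Path,
    series_description: str = "relaxmap synthetic series",
) -> list[Path]:
    """Write one standard-conformant DICOM file per frame.

    Each file carries the pixel data (16-bit unsigned, MONOCHROME2), the
    timing tags RepetitionTime (0018,0080) and EchoTime (0018,0081),
    PixelSpacing and SliceThickness.  Reading the directory back through
    :func:`catalog_series` + :func:`load_series` reproduces pixel values
    (bit-exactly for integer-stored pixels), timing lists and spacing.
    """
    series.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    series_uid = generate_uid()
    study_uid = generate_uid()
    written: list[Path] = []
    for i, frame in enumerate(series.frames):
        stored, slope, intercept = _quantize(frame.pixels)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series_description
        ds.Modality = "MR"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "SYNTH"
        ds.InstanceNumber = i + 1

        ds.RepetitionTime = frame.tr_ms
        ds.EchoTime = frame.te_ms
        ds.PixelSpacing = [frame.pixel_spacing_mm[0], frame.pixel_spacing_mm[1]]
        ds.SliceThickness = frame.slice_thickness_mm

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = np.ascontiguousarray(stored).tobytes()

        path = out / f"frame_{i:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        written.append(path)
    return written
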