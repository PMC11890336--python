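"""Resection-margin and tumor-thickness measurement.

A margin is the shortest distance from the tumor boundary to the
specimen surface within an anatomical sector (cranial, deep, caudal).
Sectors are angular wedges about the tumor centroid; their orientation
is configurable because the anatomical axes of a resected specimen
depend on how it was mounted for imaging.  Tumor thickness is the
tumor's extent along the deep axis.  The mucosal (superior) sector is
deliberately not measured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

from .core import AnnotationContour, GridSpec
from .transfer import contour_from_mask

__all__ = [
    "SectorConfig",
    "MeasurementRecord",
    "MarginResult",
    "extract_specimen_boundary",
    "measure_margin",
    "measure_thickness",
    "measure_all",
    "MEASUREMENT_REGIONS",
]

MEASUREMENT_REGIONS = ("cranial", "deep", "caudal", "thickness")


@dataclass(frozen=True)
class SectorConfig:
    """Angular sector layout about the tumor centroid.

    ``orientation_deg`` is the direction of "deep", measured from +x
    (y points downward, so the default 90 deg points to the bottom of
    the image, away from the mucosal surface).  Cranial and caudal sit
    at -90 and +90 degrees relative to deep.
    """

    orientation_deg: float = 90.0
    sector_half_angle_deg: float = 45.0
    resample_step_mm: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.sector_half_angle_deg <= 90.0):
            raise ValueError("sector_half_angle_deg must be in (0, 90]")

    def sector_center_deg(self, region: str) -> float:
        offsets = {"cranial": -90.0, "deep": 0.0, "caudal": 90.0}
        if region not in offsets:
            raise ValueError(f"unknown margin region {region!r}")
        return (self.orientation_deg + offsets[region]) % 360.0

    @property
    def deep_axis(self) -> np.ndarray:
        th = math.radians(self.orientation_deg)
        return np.array([math.cos(th), math.sin(th)])


@dataclass(frozen=True)
class MeasurementRecord:
    source: str  # US_M | US_Reg | WSI
    region: str  # cranial | deep | caudal | thickness
    value_mm: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value_mm) and self.value_mm >= 0):
            raise ValueError(f"measurement must be finite and >= 0, got {self.value_mm}")
        if self.region not in MEASUREMENT_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class MarginResult:
    distance_mm: float
    tumor_point_mm: tuple[float, float]
    specimen_point_mm: tuple[float, float]


def extract_specimen_boundary(
    specimen_mask: np.ndarray, grid: GridSpec, frame: str = "US"
) -> AnnotationContour:
    """Sub-pixel specimen outline (marching squares at 0.5) in mm."""
    mask = np.asarray(specimen_mask).astype(bool)
    if not mask.any():
        raise ValueError("specimen mask is empty")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, labels, range(1, n + 1)).astype(int)
        raise ValueError(
            f"specimen mask has {n} connected components (sizes {sorted(sizes)}); "
            "expected a single specimen"
        )
    return contour_from_mask(mask, grid, source="truth", frame=frame)


def _resample_closed(vertices: np.ndarray, step_mm: float) -> np.ndarray:
    """Evenly resample a closed polygon boundary at ~step_mm spacing."""
    ring = np.vstack([vertices, vertices[:1]])
    line = LineString(ring)
    n = max(int(np.ceil(line.length / step_mm)), 8)
    dists = np.linspace(0.0, line.length, n, endpoint=False)
    pts = [line.interpolate(d) for d in dists]
    return np.array([[p.x, p.y] for p in pts])


def _in_wedge(points: np.ndarray, center: np.ndarray, center_deg: float, half_deg: float) -> np.ndarray:
    ang = np.degrees(np.arctan2(points[:, 1] - center[1], points[:, 0] - center[0]))
    delta = (ang - center_deg + 180.0) % 360.0 - 180.0
    return np.abs(delta) <= half_deg


def measure_margin(
    tumor_contour: AnnotationContour,
    specimen_contour: AnnotationContour,
    region: str,
    config: SectorConfig | None = None,
) -> MarginResult:
    """Minimum tumor-to-specimen boundary distance within one sector.

    Both boundaries are densely resampled; points are kept if they fall
    inside the sector's wedge about the tumor centroid, and the minimum
    pairwise Euclidean distance (with the realizing point pair) is
    returned.
    """
    config = config or SectorConfig()
    center_deg = config.sector_center_deg(region)
    tum = _resample_closed(np.asarray(tumor_contour.vertices, float), config.resample_step_mm)
    spec_pts = _resample_closed(
        np.asarray(specimen_contour.vertices, float), config.resample_step_mm
    )
    centroid = _polygon_centroid(tumor_contour.vertices)
    tum_sel = tum[_in_wedge(tum, centroid, center_deg, config.sector_half_angle_deg)]
    spec_sel = spec_pts[_in_wedge(spec_pts, centroid, center_deg, config.sector_half_angle_deg)]
    if len(tum_sel) == 0 or len(spec_sel) == 0:
        raise ValueError(f"sector empty: no boundary points fall in the {region!r} wedge")
    d2 = ((tum_sel[:, None, :] - spec_sel[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return MarginResult(
        distance_mm=float(np.sqrt(d2[i, j])),
        tumor_point_mm=tuple(tum_sel[i]),
        specimen_point_mm=tuple(spec_sel[j]),
    )


def measure_thickness(
    tumor_contour: AnnotationContour, config: SectorConfig | None = None
) -> float:
    """Maximal tumor extent along the deep axis (mm)."""
    config = config or SectorConfig()
    verts = np.asarray(tumor_contour.vertices, dtype=float)
    if len(verts) < 3:
        raise ValueError("degenerate contour")
    proj = verts @ config.deep_axis
    extent = float(proj.max() - proj.min())
    if extent <= 0:
        raise ValueError("degenerate contour: zero extent along deep axis")
    return extent


def _polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    from shapely.geometry import Polygon

    c = Polygon(vertices).centroid
    return np.array([c.x, c.y])


def _measure_source(
    tumor: AnnotationContour,
    specimen: AnnotationContour,
    source: str,
    slide_id: str,
    config: SectorConfig,
) -> list[MeasurementRecord]:
    records = []
    for region in ("cranial", "deep", "caudal"):
        m = measure_margin(tumor, specimen, region, config)
        records.append(MeasurementRecord(source, region, m.distance_mm, slide_id))
    records.append(
        MeasurementRecord(source, "thickness", measure_thickness(tumor, config), slide_id)
    )
    return records


def measure_all(pair, registration, config: SectorConfig | None = None) -> list[MeasurementRecord]:
    """All margin/thickness records for one slice pair.

    Three annotation sources are measured when available: the manual US
    annotation (US_M) and the registered pathologist annotation (US_Reg)
    against the US specimen boundary, and the pathologist annotation
    (HTA) against the WSI specimen boundary.  Missing sources are
    skipped with a warning.
    """
    from .transfer import transform_contour

    config = config or SectorConfig()
    records: list[MeasurementRecord] = []

    us_boundary = wsi_boundary = None
    if pair.us_specimen_mask is not None:
        us_boundary = extract_specimen_boundary(pair.us_specimen_mask, pair.grid, frame="US")
    if pair.wsi_specimen_mask is not None:
        wsi_boundary = extract_specimen_boundary(pair.wsi_specimen_mask, pair.grid, frame="WSI")

    if pair.us_manual_tumor is not None and us_boundary is not None:
        records += _measure_source(pair.us_manual_tumor, us_boundary, "US_M", pair.slide_id, config)
    else:
        warnings.warn(f"slide {pair.slide_id}: US_M annotation missing; skipped")

    if pair.hta is not None and us_boundary is not None and registration is not None:
        us_reg = transform_contour(
            pair.hta, registration.best_transform, inverse=True, source="US_Reg", frame="US"
        )
        records += _measure_source(us_reg, us_boundary, "US_Reg", pair.slide_id, config)
    else:
        warnings.warn(f"slide {pair.slide_id}: registered annotation unavailable; skipped")

    if pair.hta is not None and wsi_boundary is not None:
        records += _measure_source(pair.hta, wsi_boundary, "WSI", pair.slide_id, config)
    else:
        warnings.warn(f"slide {pair.slide_id}: WSI annotation missing; skipped")

    return records
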