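"""Core domain types shared across the pipeline.

Coordinate convention
---------------------
All physical coordinates are 2D, in millimetres, with the origin at the
image corner, x pointing rightward (columns) and y pointing downward
(rows).  The centre of pixel ``(i, j)`` (row i, column j) sits at

    origin + ((j + 0.5) * sx, (i + 0.5) * sy)

where ``(sx, sy)`` is the pixel spacing.  3D Slicer markup files use RAS;
``(R, A)`` maps to ``(x, -y)`` in this frame (see :mod:`ushisto.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Image2D",
    "Landmark",
    "Transform2D",
    "AnnotationContour",
    "SlicePair",
    "GridSpec",
    "ROLE_CIRCUMFERENTIAL",
    "FIDUCIAL_ROLES",
    "LANDMARK_ROLES",
    "LABEL_BACKGROUND",
    "LABEL_SPECIMEN",
    "LABEL_TUMOR",
]

ROLE_CIRCUMFERENTIAL = "circumferential"
FIDUCIAL_ROLES = ("fiducial_left", "fiducial_middle", "fiducial_right")
LANDMARK_ROLES = (ROLE_CIRCUMFERENTIAL,) + FIDUCIAL_ROLES

# label-map scheme: background / specimen / tumor
LABEL_BACKGROUND = 0
LABEL_SPECIMEN = 1
LABEL_TUMOR = 2


@dataclass(frozen=True)
class GridSpec:
    """Raster geometry: shape (rows, cols), pixel spacing and origin in mm."""

    shape: tuple[int, int]
    spacing_mm: tuple[float, float]  # (sx, sy) = (col, row) spacing
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_mm[0] <= 0 or self.spacing_mm[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing_mm}")

    def pixel_centers(self) -> np.ndarray:
        """(rows*cols, 2) array of pixel-centre (x, y) positions in mm."""
        rows, cols = self.shape
        sx, sy = self.spacing_mm
        ox, oy = self.origin_mm
        jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
        x = ox + (jj + 0.5) * sx
        y = oy + (ii + 0.5) * sy
        return np.column_stack([x.ravel(), y.ravel()])

    def index_to_mm(self, rc: np.ndarray) -> np.ndarray:
        """Map fractional (row, col) indices to physical (x, y) mm."""
        rc = np.atleast_2d(np.asarray(rc, dtype=float))
        sx, sy = self.spacing_mm
        ox, oy = self.origin_mm
        return np.column_stack([ox + (rc[:, 1] + 0.5) * sx, oy + (rc[:, 0] + 0.5) * sy])


@dataclass(frozen=True)
class Image2D:
    """A single 2D image with explicit physical geometry."""

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.intensities.ndim != 2:
            raise ValueError("Image2D expects a 2D array")
        if self.pixel_spacing_mm[0] <= 0 or self.pixel_spacing_mm[1] <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.intensities.shape, self.pixel_spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class Landmark:
    """A role-tagged physical point in one modality.

    ``role`` is ``circumferential`` or one of the fiducial roles; within
    one point list a fiducial role may appear at most once.
    """

    label: str
    role: str
    position_mm: tuple[float, float]
    modality: str  # "US" or "WSI"

    def __post_init__(self) -> None:
        if self.role not in LANDMARK_ROLES:
            raise ValueError(
                f"unknown landmark role {self.role!r}; allowed: {LANDMARK_ROLES}"
            )
        if self.modality not in ("US", "WSI"):
            raise ValueError(f"modality must be 'US' or 'WSI', got {self.modality!r}")
        if not (math.isfinite(self.position_mm[0]) and math.isfinite(self.position_mm[1])):
            raise ValueError(f"landmark position must be finite, got {self.position_mm}")


class Transform2D:
    """A 2D homogeneous transform (3x3 matrix), last row (0, 0, 1).

    ``model`` records the family the matrix was estimated under
    (rigid / similarity / affine); the matrix itself is always applied
    as a general affine map.
    """

    __slots__ = ("matrix", "model")

    def __init__(self, matrix: np.ndarray, model: str = "affine") -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError("Transform2D expects a 3x3 matrix")
        if not np.allclose(matrix[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row of a 2D homogeneous transform must be (0,0,1)")
        if model not in ("rigid", "similarity", "affine"):
            raise ValueError(f"unknown transform model {model!r}")
        if abs(np.linalg.det(matrix[:2, :2])) < 1e-15:
            raise ValueError("transform is singular")
        self.matrix = matrix
        self.model = model

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls, model: str = "rigid") -> "Transform2D":
        return cls(np.eye(3), model=model)

    @classmethod
    def from_similarity(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation_mm: Sequence[float] = (0.0, 0.0),
    ) -> "Transform2D":
        th = math.radians(rotation_deg)
        c, s = math.cos(th), math.sin(th)
        m = np.array(
            [
                [scale * c, -scale * s, translation_mm[0]],
                [scale * s, scale * c, translation_mm[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(m, model="similarity" if scale != 1.0 else "rigid")

    # -- application ----------------------------------------------------
    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of points (a single (2,) point is fine)."""
        pts = np.asarray(points_mm, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out[0] if single else out

    def inverse(self) -> "Transform2D":
        return Transform2D(np.linalg.inv(self.matrix), model=self.model)

    def compose(self, other: "Transform2D") -> "Transform2D":
        """Return the transform 'self after other' (self @ other)."""
        return Transform2D(self.matrix @ other.matrix, model="affine")

    # -- decomposition (meaningful for rigid/similarity) ----------------
    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    @property
    def translation_mm(self) -> tuple[float, float]:
        return (float(self.matrix[0, 2]), float(self.matrix[1, 2]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Transform2D(model={self.model!r}, matrix=\n{self.matrix})"


@dataclass(frozen=True)
class AnnotationContour:
    """A closed simple polygon (mm) carrying a tumor annotation.

    ``source`` is one of HTA (pathologist annotation on the whole-slide
    image), US_M (manual ultrasound annotation) or US_Reg (HTA mapped
    into the ultrasound frame); ``frame`` names the coordinate frame the
    vertices live in.
    """

    vertices: np.ndarray  # (N, 2), closed implicitly (last != first)
    source: str
    frame: str

    _SOURCES = ("HTA", "US_M", "US_Reg", "truth")
    _FRAMES = ("US", "WSI")

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs an (N>=3, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("contour vertices must be finite")
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown contour source {self.source!r}")
        if self.frame not in self._FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")

    def shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    @property
    def is_simple(self) -> bool:
        return bool(self.shapely().is_valid)

    def area_mm2(self) -> float:
        return float(abs(self.shapely().area))


@dataclass
class SlicePair:
    """One corresponding US slice / histology slide with their annotations."""

    slide_id: str
    patient_index: int
    slice_index: int
    us_image: Image2D | None
    wsi_image: Image2D | None
    us_specimen_mask: np.ndarray | None
    wsi_specimen_mask: np.ndarray | None
    us_landmarks: list[Landmark] = field(default_factory=list)
    wsi_landmarks: list[Landmark] = field(default_factory=list)
    us_manual_tumor: AnnotationContour | None = None  # US_M
    hta: AnnotationContour | None = None  # pathologist annotation, WSI frame
    us_tumor_mask: np.ndarray | None = None  # rasterized US_M
    wsi_tumor_mask: np.ndarray | None = None  # rasterized HTA
    grid: GridSpec | None = None
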