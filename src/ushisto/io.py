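"""File formats: NRRD/NIfTI volumes, 3D Slicer markups (FCSV + JSON),
raster exports and CSV reports.

Spacing is never guessed: a volume file without explicit spacing
metadata is rejected rather than silently treated as 1 mm isotropic.

Coordinate mapping for Slicer markups: the internal frame is 2D with x
rightward and y downward (image convention); Slicer stores RAS (or LPS)
world coordinates.  ``(R, A)`` maps to ``(x, -y)`` — and therefore
``(L, P)`` to ``(-x, y)`` — with the slice coordinate in S, which is
ignored on read and written as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FIDUCIAL_ROLES, LANDMARK_ROLES, ROLE_CIRCUMFERENTIAL, Landmark

__all__ = [
    "FormatError",
    "VolumeStack",
    "read_volume",
    "write_volume",
    "read_pointlist",
    "write_pointlist",
    "write_report",
    "write_study",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


@dataclass(frozen=True)
class VolumeStack:
    """A stack of 2D slices with explicit anisotropic spacing.

    ``voxels`` is (n_slices, rows, cols); ``spacing_mm`` is (sx, sy, sz)
    with sz the slice spacing.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("VolumeStack expects a 3D array (slices, rows, cols)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def _nrrd_header_has_spacing(path: Path) -> bool:
    """Inspect the plain-text NRRD header for explicit spacing metadata."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(8192).decode("ascii", errors="replace")
    except OSError as exc:  # pragma: no cover
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not head.startswith("NRRD"):
        raise FormatError(f"{path} is not an NRRD file (missing magic)")
    keys = [line.split(":")[0].strip().lower() for line in head.splitlines() if ":" in line]
    return "spacings" in keys or "space directions" in keys


def read_volume(path) -> VolumeStack:
    """Read an NRRD or NIfTI volume with its spacing.

    Raises :class:`FormatError` for malformed files and for volumes
    without explicit spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".nrrd") or suffix.endswith(".nhdr"):
        return _read_nrrd(path)
    if suffix.endswith(".nii") or suffix.endswith(".nii.gz"):
        return _read_nifti(path)
    raise FormatError(f"unsupported volume format: {path.name}")


def _read_nrrd(path: Path) -> VolumeStack:
    import SimpleITK as sitk

    if not _nrrd_header_has_spacing(path):
        raise FormatError(
            f"{path} has no 'spacings' or 'space directions' field; "
            "refusing to assume 1 mm voxels"
        )
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"malformed NRRD {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim == 2:
        arr = arr[None]
    sx, sy, sz = (img.GetSpacing() + (1.0,))[:3]
    origin = (img.GetOrigin() + (0.0,))[:3]
    return VolumeStack(arr, (float(sx), float(sy), float(sz)), tuple(map(float, origin)))


def _read_nifti(path: Path) -> VolumeStack:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"malformed NIfTI {path}: {exc}") from exc
    affine = img.affine
    # voxel sizes = column norms of the affine's linear part
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise FormatError(f"{path} has a degenerate affine; spacing undefined")
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 2:
        arr = arr[..., None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    # nibabel axis order is (x, y, z); reorder to (slices, rows, cols)
    voxels = np.transpose(arr, (2, 1, 0))
    origin = tuple(float(v) for v in affine[:3, 3])
    return VolumeStack(
        voxels, (float(spacing[0]), float(spacing[1]), float(spacing[2])), origin
    )


def write_volume(stack: VolumeStack, path) -> None:
    """Write a VolumeStack as NRRD (via SimpleITK) or NIfTI (via nibabel)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".nrrd") or suffix.endswith(".nhdr"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(stack.voxels)
        img.SetSpacing(tuple(float(s) for s in stack.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in stack.origin_mm))
        sitk.WriteImage(img, str(path), useCompression=False)
    elif suffix.endswith(".nii") or suffix.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag(list(stack.spacing_mm) + [1.0])
        affine[:3, 3] = stack.origin_mm
        arr = np.transpose(stack.voxels, (2, 1, 0))
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    else:
        raise FormatError(f"unsupported volume format: {path.name}")


# --------------------------------------------------------------------------
# point lists (3D Slicer markups)
# --------------------------------------------------------------------------

def _role_from_label(label: str) -> str:
    low = label.strip().lower()
    if low in FIDUCIAL_ROLES:
        return low
    if low.startswith(("fiducial", "fid")):
        for role in FIDUCIAL_ROLES:
            side = role.split("_")[1]
            if low.endswith(side):
                return role
        raise FormatError(
            f"unknown fiducial role label {label!r}; allowed roles: {list(LANDMARK_ROLES)}"
        )
    return ROLE_CIRCUMFERENTIAL


def _ras_to_internal(r: float, a: float) -> tuple[float, float]:
    return (r, -a)


def _internal_to_ras(x: float, y: float) -> tuple[float, float]:
    return (x, -y)


def _check_roles(landmarks: list[Landmark]) -> list[Landmark]:
    seen: set[str] = set()
    for lm in landmarks:
        if lm.role in FIDUCIAL_ROLES:
            if lm.role in seen:
                raise FormatError(f"duplicate fiducial role {lm.role!r} in point list")
            seen.add(lm.role)
    return landmarks


def read_pointlist(path, modality: str = "US") -> list[Landmark]:
    """Read a Slicer markups point list (FCSV or markups JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".fcsv":
        return _read_fcsv(path, modality)
    if path.suffix.lower() == ".json":
        return _read_markups_json(path, modality)
    raise FormatError(f"unsupported point-list format: {path.name}")


def _read_fcsv(path: Path, modality: str) -> list[Landmark]:
    coord = "RAS"
    landmarks: list[Landmark] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                low = line.lower()
                if "coordinatesystem" in low:
                    val = line.split("=")[-1].strip().upper()
                    coord = "LPS" if val in ("LPS", "1") else "RAS"
                continue
            fields = line.split(",")
            if len(fields) < 12:
                raise FormatError(f"{path}: FCSV row has {len(fields)} fields, expected >= 12")
            try:
                c1, c2 = float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric coordinate in row {fields[0]!r}") from exc
            label = fields[11]
            if coord == "LPS":
                c1, c2 = -c1, -c2  # LPS -> RAS
            x, y = _ras_to_internal(c1, c2)
            landmarks.append(Landmark(label, _role_from_label(label), (x, y), modality))
    return _check_roles(landmarks)


def _read_markups_json(path: Path, modality: str) -> list[Landmark]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed markups JSON {path}: {exc}") from exc
    if "markups" not in doc:
        raise FormatError(f"{path}: missing 'markups' field")
    landmarks: list[Landmark] = []
    for markup in doc["markups"]:
        coord = markup.get("coordinateSystem", "LPS").upper()
        for cp in markup.get("controlPoints", []):
            pos = cp.get("position")
            if pos is None or len(pos) < 2:
                raise FormatError(f"{path}: control point without position")
            c1, c2 = float(pos[0]), float(pos[1])
            if coord == "LPS":
                c1, c2 = -c1, -c2
            x, y = _ras_to_internal(c1, c2)
            label = cp.get("label", "")
            landmarks.append(Landmark(label, _role_from_label(label), (x, y), modality))
    return _check_roles(landmarks)


def write_pointlist(landmarks: list[Landmark], path) -> None:
    """Write landmarks as FCSV or markups JSON (by extension), RAS coords."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _check_roles(list(landmarks))
    if path.suffix.lower() == ".fcsv":
        lines = [
            "# Markups fiducial file version = 4.11",
            "# CoordinateSystem = RAS",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
        ]
        for i, lm in enumerate(landmarks):
            r, a = _internal_to_ras(*lm.position_mm)
            lines.append(
                f"vtkMRMLMarkupsFiducialNode_{i},{r:.9f},{a:.9f},0,0,0,0,1,1,1,0,{lm.label},,"
            )
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix.lower() == ".json":
        control_points = []
        for i, lm in enumerate(landmarks):
            r, a = _internal_to_ras(*lm.position_mm)
            control_points.append(
                {
                    "id": str(i + 1),
                    "label": lm.label,
                    "position": [r, a, 0.0],
                    "orientation": [-1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0],
                }
            )
        doc = {
            "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
            "markups": [
                {
                    "type": "Fiducial",
                    "coordinateSystem": "RAS",
                    "coordinateUnits": "mm",
                    "controlPoints": control_points,
                }
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise FormatError(f"unsupported point-list format: {path.name}")


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def write_report(tables: dict[str, pd.DataFrame], outdir) -> list[Path]:
    """Write one CSV per named table; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    return written


def write_study(study, outdir) -> Path:
    """Write a phantom study to disk in the pipeline's exchange formats.

    Per slide: the US slice and masks as NRRD, the histology raster as
    PNG, and both point lists as FCSV and markups JSON; plus the study
    manifest as CSV.  Returns the manifest path.
    """
    from PIL import Image as PILImage

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = study.spec
    sp = spec.pixel_spacing_mm
    for pair in study.pairs:
        d = outdir / pair.slide_id
        d.mkdir(exist_ok=True)
        if pair.us_image is not None:
            write_volume(
                VolumeStack(pair.us_image.intensities[None], (sp, sp, spec.slice_spacing_mm)),
                d / "us.nrrd",
            )
            write_volume(
                VolumeStack(
                    (pair.us_specimen_mask + pair.us_tumor_mask).astype(np.uint8)[None],
                    (sp, sp, spec.slice_spacing_mm),
                ),
                d / "us_labels.nrrd",
            )
            write_volume(
                VolumeStack(
                    (pair.wsi_specimen_mask + pair.wsi_tumor_mask).astype(np.uint8)[None],
                    (sp, sp, spec.slice_spacing_mm),
                ),
                d / "wsi_labels.nrrd",
            )
        if pair.wsi_image is not None:
            arr = (np.clip(pair.wsi_image.intensities, 0, 1) * 255).astype(np.uint8)
            PILImage.fromarray(arr).save(d / "wsi.png")
        write_pointlist(pair.us_landmarks, d / "us_points.fcsv")
        write_pointlist(pair.us_landmarks, d / "us_points.json")
        write_pointlist(pair.wsi_landmarks, d / "wsi_points.fcsv")
        write_pointlist(pair.wsi_landmarks, d / "wsi_points.json")
    manifest_path = outdir / "manifest.csv"
    study.manifest.to_csv(manifest_path, index=False)
    return manifest_path
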