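"""Synthetic specimen phantom: paired US-like slices and histology-like slides.

The study this pipeline emulates registers intraoperative 3D ultrasound
slices of resected tongue specimens to their histopathology sections.
Patient data of that kind are not public, so every downstream stage is
exercised on a phantom with known ground truth instead:

* a specimen cross-section — a smooth single blob (ellipse with
  low-frequency radial perturbation) containing a tumor blob strictly
  inside it and up to three fiducial cannula tracks along the long axis;
* a histology counterpart produced by a *known* similarity transform
  (in-plane rotation, isotropic fixation shrinkage, translation), with
  an optional smooth residual deformation field on top;
* landmark lists for both modalities with Gaussian selection jitter;
* a noisier "manual" US tumor annotation, emulating the human annotator.

Randomness is split into independent streams per (patient, slice,
purpose), so e.g. turning on annotation noise does not reshuffle the
landmark jitter of the same slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import (
    FIDUCIAL_ROLES,
    ROLE_CIRCUMFERENTIAL,
    AnnotationContour,
    GridSpec,
    Image2D,
    Landmark,
    SlicePair,
    Transform2D,
)
from .margins import SectorConfig, measure_margin, measure_thickness
from .transfer import contour_from_mask, rasterize_contour

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomStudy",
    "GenerationError",
    "generate_specimen_slice",
    "simulate_manual_us_annotation",
    "generate_study",
]

# RNG stream purposes (kept stable so adding a stage never reshuffles another)
_P_PATIENT = 0
_P_GEOMETRY = 1
_P_JITTER_US = 2
_P_JITTER_WSI = 3
_P_DEFORM = 4
_P_MANUAL = 5
_P_STUDY = 6

_MIN_TUMOR_MARGIN_MM = 0.8  # generation constraint, not a measured quantity


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the phantom generator.

    The defaults describe one synthetic cohort: 8 patients x 4 slices
    (29 retained after exclusions), 0.076 mm in-plane pixel spacing,
    0.9 isotropic US→histology shrinkage, 0.1 mm landmark-selection
    jitter and 1.0 mm manual-annotation boundary noise.
    """

    seed: int = 0
    n_patients: int = 8
    slices_per_patient: int = 4
    pixel_spacing_mm: float = 0.076
    image_size_px: tuple[int, int] = (384, 512)  # (rows, cols)
    shrinkage_factor: float = 0.90
    rotation_deg: float = 6.0
    translation_mm: tuple[float, float] = (1.2, 0.8)
    residual_deformation_amplitude_mm: float = 0.0
    landmark_jitter_sd_mm: float = 0.1
    annotation_noise_sd_mm: float = 1.0
    n_fiducials: int = 3
    n_circumferential: int = 8
    slice_spacing_mm: float = 0.5
    exclusion_fraction: float = 3.0 / 32.0

    def __post_init__(self) -> None:
        if not (0.0 < self.shrinkage_factor <= 1.0):
            raise ValueError("shrinkage_factor must be in (0, 1]")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.n_fiducials not in (1, 2, 3):
            raise ValueError("n_fiducials must be 1, 2 or 3")
        if self.n_circumferential < 4:
            raise ValueError("n_circumferential must be >= 4")
        for name in (
            "residual_deformation_amplitude_mm",
            "landmark_jitter_sd_mm",
            "annotation_noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_patients < 0 or self.slices_per_patient < 0:
            raise ValueError("counts must be non-negative")

    @property
    def grid(self) -> GridSpec:
        s = self.pixel_spacing_mm
        return GridSpec(self.image_size_px, (s, s))


@dataclass
class PhantomTruth:
    """Ground truth the real study lacks: the generating transform,
    noise-free masks/contours, and the true margins and thickness."""

    true_transform: Transform2D  # US frame -> histology frame
    true_specimen_mask: dict  # modality -> binary grid (None when not rasterized)
    true_tumor_mask: dict
    true_margins_mm: dict  # region -> mm, in the US frame
    true_thickness_mm: float
    fiducial_positions_mm: list  # [(us_xy, wsi_xy), ...] jitter-free
    true_specimen_contour: dict = field(default_factory=dict)  # modality -> (N,2) mm
    true_tumor_contour: dict = field(default_factory=dict)


@dataclass
class PhantomStudy:
    spec: PhantomSpec
    pairs: list
    truths: list
    manifest: pd.DataFrame

    def included(self):
        """(SlicePair, PhantomTruth) tuples retained for analysis."""
        keep = set(self.manifest.loc[self.manifest["included"], "slide_id"])
        return [
            (p, t) for p, t in zip(self.pairs, self.truths) if p.slide_id in keep
        ]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _fourier_radial_field(theta: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean field over angle with pointwise SD = sd.

    Sum of low-frequency Fourier modes; each angle's value is Gaussian
    with variance sd^2 because the per-mode variances add to sd^2.
    """
    weights = np.array([0.5, 1.0, 1.0, 0.8, 0.6, 0.4, 0.2])
    var = sd * sd * weights / weights.sum()
    out = np.zeros_like(theta)
    for k, v in enumerate(var):
        s = np.sqrt(v)
        if k == 0:
            out += rng.normal(0.0, s) * np.ones_like(theta)
        else:
            out += rng.normal(0.0, s) * np.cos(k * theta)
            out += rng.normal(0.0, s) * np.sin(k * theta)
    return out


def _blob(
    center: np.ndarray,
    semi_axes: tuple[float, float],
    rng: np.random.Generator,
    n_vertices: int = 256,
    perturbation: float = 0.03,
) -> np.ndarray:
    """Closed smooth blob: ellipse with low-frequency radial perturbation."""
    a, b = semi_axes
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    bump = np.zeros_like(theta)
    for k in (2, 3, 4):
        amp = rng.uniform(0.2, 1.0) * perturbation
        phase = rng.uniform(0.0, 2.0 * np.pi)
        bump += amp * np.cos(k * theta + phase)
    r = r_ell * (1.0 + bump)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _similarity_about(
    center: np.ndarray, scale: float, rotation_deg: float, translation: tuple[float, float]
) -> Transform2D:
    """Similarity that scales/rotates about ``center`` then translates."""
    pre = Transform2D.from_similarity(1.0, 0.0, (-center[0], -center[1]))
    mid = Transform2D.from_similarity(scale, rotation_deg, (0.0, 0.0))
    post = Transform2D.from_similarity(
        1.0, 0.0, (center[0] + translation[0], center[1] + translation[1])
    )
    m = post.matrix @ mid.matrix @ pre.matrix
    return Transform2D(m, model="similarity" if scale != 1.0 else "rigid")


def _deformation_field(spec: PhantomSpec, rng: np.random.Generator):
    """Coarse 3x3 control-point displacement field, smoothly interpolated.

    Returns a callable points(N,2)->displacements(N,2); the identity
    callable when the amplitude is zero.
    """
    amp = spec.residual_deformation_amplitude_mm
    if amp == 0.0:
        return lambda pts: np.zeros_like(np.atleast_2d(pts), dtype=float)
    from scipy.interpolate import RectBivariateSpline

    rows, cols = spec.image_size_px
    extent_x = cols * spec.pixel_spacing_mm
    extent_y = rows * spec.pixel_spacing_mm
    xs = np.linspace(0.0, extent_x, 3)
    ys = np.linspace(0.0, extent_y, 3)
    dx = rng.normal(0.0, amp, size=(3, 3))
    dy = rng.normal(0.0, amp, size=(3, 3))
    fx = RectBivariateSpline(ys, xs, dx, kx=2, ky=2)
    fy = RectBivariateSpline(ys, xs, dy, kx=2, ky=2)

    def field(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.column_stack(
            [fx(pts[:, 1], pts[:, 0], grid=False), fy(pts[:, 1], pts[:, 0], grid=False)]
        )

    return field


def _sample_geometry(spec: PhantomSpec, patient_index: int, slice_index: int):
    """Specimen/tumor polygons and fiducials in the US frame."""
    prng = _rng(spec.seed, patient_index, _P_PATIENT)
    a0 = prng.uniform(11.5, 16.0)
    b0 = prng.uniform(7.5, 12.5)
    at0 = prng.uniform(3.2, 0.42 * a0)
    bt0 = prng.uniform(2.4, 0.66 * b0)
    dx0 = prng.uniform(-2.5, 2.5)
    dy0 = prng.uniform(0.3, 1.6)

    grng = _rng(spec.seed, patient_index, _P_GEOMETRY, slice_index)
    rows, cols = spec.image_size_px
    center = np.array(
        [0.5 * cols * spec.pixel_spacing_mm, 0.5 * rows * spec.pixel_spacing_mm]
    )
    sf = grng.uniform(0.90, 1.0)  # slice-to-slice size variation through the volume
    a, b = a0 * sf, b0 * sf
    specimen = _blob(center, (a, b), grng, perturbation=0.03)
    specimen_poly = Polygon(specimen)

    at, bt = at0 * sf, bt0 * sf
    t_center = center + np.array([dx0, dy0]) + grng.normal(0.0, 0.3, size=2)
    tumor = _blob(t_center, (at, bt), grng, n_vertices=192, perturbation=0.05)
    for _ in range(12):
        if Polygon(tumor).within(specimen_poly.buffer(-_MIN_TUMOR_MARGIN_MM)):
            break
        at, bt = 0.9 * at, 0.9 * bt
        t_center = center + 0.8 * (t_center - center)
        tumor = _blob(t_center, (at, bt), grng, n_vertices=192, perturbation=0.05)
    else:
        raise GenerationError(
            f"tumor cannot be placed inside specimen at the requested "
            f"{_MIN_TUMOR_MARGIN_MM} mm minimum margin "
            f"(patient {patient_index}, slice {slice_index})"
        )

    roles = list(FIDUCIAL_ROLES[: spec.n_fiducials])
    fractions = {"fiducial_left": -0.55, "fiducial_middle": 0.0, "fiducial_right": 0.55}
    fiducials = {r: center + np.array([fractions[r] * a, 0.0]) for r in roles}
    return specimen, tumor, fiducials, center


def generate_specimen_slice(
    spec: PhantomSpec,
    patient_index: int,
    slice_index: int,
    rasterize: bool = True,
) -> tuple[SlicePair, PhantomTruth]:
    """One paired US slice / histology slide with its ground truth.

    With ``rasterize=False`` only the vector geometry (landmarks and
    contours) is produced — enough for registration experiments and
    considerably faster for large replicate sweeps.
    """
    if not (0 <= patient_index < max(spec.n_patients, 1)):
        raise ValueError(f"patient_index {patient_index} out of range")
    if not (0 <= slice_index < max(spec.slices_per_patient, 1)):
        raise ValueError(f"slice_index {slice_index} out of range")

    specimen_us, tumor_us, fid_us, center = _sample_geometry(spec, patient_index, slice_index)
    transform = _similarity_about(
        center, spec.shrinkage_factor, spec.rotation_deg, spec.translation_mm
    )
    deform = _deformation_field(spec, _rng(spec.seed, patient_index, _P_DEFORM, slice_index))

    specimen_wsi = transform.apply(specimen_us)
    specimen_wsi = specimen_wsi + deform(specimen_wsi)
    tumor_wsi = transform.apply(tumor_us)
    tumor_wsi = tumor_wsi + deform(tumor_wsi)

    # --- landmark lists ------------------------------------------------
    jrng_us = _rng(spec.seed, patient_index, _P_JITTER_US, slice_index)
    jrng_wsi = _rng(spec.seed, patient_index, _P_JITTER_WSI, slice_index)
    sd = spec.landmark_jitter_sd_mm
    idx = np.linspace(0, len(specimen_us), spec.n_circumferential, endpoint=False).astype(int)

    us_landmarks, wsi_landmarks = [], []
    for k, i in enumerate(idx):
        label = f"circ-{k + 1:02d}"
        pu = specimen_us[i] + jrng_us.normal(0.0, sd, 2)
        pw = specimen_wsi[i] + jrng_wsi.normal(0.0, sd, 2)
        us_landmarks.append(Landmark(label, ROLE_CIRCUMFERENTIAL, tuple(pu), "US"))
        wsi_landmarks.append(Landmark(label, ROLE_CIRCUMFERENTIAL, tuple(pw), "WSI"))

    fiducial_truth = []
    for role, p_us in fid_us.items():
        p_wsi = transform.apply(p_us)
        fiducial_truth.append((tuple(p_us), tuple(p_wsi)))
        pu = p_us + jrng_us.normal(0.0, sd, 2)
        pw = p_wsi + jrng_wsi.normal(0.0, sd, 2)
        us_landmarks.append(Landmark(role, role, tuple(pu), "US"))
        wsi_landmarks.append(Landmark(role, role, tuple(pw), "WSI"))

    # --- annotations ----------------------------------------------------
    mrng = _rng(spec.seed, patient_index, _P_MANUAL, slice_index)
    manual_vertices = _perturb_polygon_radial(tumor_us, spec.annotation_noise_sd_mm, mrng)
    us_manual = AnnotationContour(manual_vertices, source="US_M", frame="US")
    hta = AnnotationContour(tumor_wsi, source="HTA", frame="WSI")

    # --- ground-truth measurements (on exact polygons) ------------------
    truth_spec_c = AnnotationContour(specimen_us, source="truth", frame="US")
    truth_tum_c = AnnotationContour(tumor_us, source="truth", frame="US")
    sectors = SectorConfig()
    margins = {
        r: measure_margin(truth_tum_c, truth_spec_c, r, sectors).distance_mm
        for r in ("cranial", "deep", "caudal")
    }
    thickness = measure_thickness(truth_tum_c, sectors)

    grid = spec.grid
    us_image = wsi_image = None
    masks: dict[str, dict[str, np.ndarray | None]] = {
        "specimen": {"US": None, "WSI": None},
        "tumor": {"US": None, "WSI": None},
    }
    us_tumor_mask = wsi_tumor_mask = None
    if rasterize:
        spec_us_mask = rasterize_contour(truth_spec_c, grid)
        tum_us_mask = rasterize_contour(truth_tum_c, grid)
        spec_wsi_mask = rasterize_contour(
            AnnotationContour(specimen_wsi, source="truth", frame="WSI"), grid
        )
        tum_wsi_mask = rasterize_contour(hta, grid)
        masks["specimen"] = {"US": spec_us_mask, "WSI": spec_wsi_mask}
        masks["tumor"] = {"US": tum_us_mask, "WSI": tum_wsi_mask}
        us_tumor_mask = rasterize_contour(us_manual, grid)
        wsi_tumor_mask = tum_wsi_mask
        us_image = Image2D(
            (0.12 + 0.33 * spec_us_mask + 0.30 * tum_us_mask).astype(np.float32),
            (spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        )
        wsi_image = Image2D(
            (0.92 - 0.30 * spec_wsi_mask - 0.35 * tum_wsi_mask).astype(np.float32),
            (spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        )

    slide_id = f"P{patient_index:02d}-S{slice_index:02d}"
    pair = SlicePair(
        slide_id=slide_id,
        patient_index=patient_index,
        slice_index=slice_index,
        us_image=us_image,
        wsi_image=wsi_image,
        us_specimen_mask=masks["specimen"]["US"],
        wsi_specimen_mask=masks["specimen"]["WSI"],
        us_landmarks=us_landmarks,
        wsi_landmarks=wsi_landmarks,
        us_manual_tumor=us_manual,
        hta=hta,
        us_tumor_mask=us_tumor_mask,
        wsi_tumor_mask=wsi_tumor_mask,
        grid=grid,
    )
    truth = PhantomTruth(
        true_transform=transform,
        true_specimen_mask={m: masks["specimen"][m] for m in ("US", "WSI")},
        true_tumor_mask={m: masks["tumor"][m] for m in ("US", "WSI")},
        true_margins_mm=margins,
        true_thickness_mm=thickness,
        fiducial_positions_mm=fiducial_truth,
        true_specimen_contour={"US": specimen_us, "WSI": specimen_wsi},
        true_tumor_contour={"US": tumor_us, "WSI": tumor_wsi},
    )
    return pair, truth


def _perturb_polygon_radial(
    vertices: np.ndarray, noise_sd_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace a star-shaped polygon boundary by a smooth radial field."""
    vertices = np.asarray(vertices, dtype=float)
    if noise_sd_mm == 0.0:
        return vertices.copy()
    centroid = np.array(Polygon(vertices).centroid.coords[0])
    rel = vertices - centroid
    r = np.linalg.norm(rel, axis=1)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    f = _fourier_radial_field(theta, noise_sd_mm, rng)
    r_new = np.maximum(r + f, 0.2 * r)  # keep the polygon from collapsing
    return centroid + np.column_stack([r_new * np.cos(theta), r_new * np.sin(theta)])


def simulate_manual_us_annotation(
    true_tumor_mask: np.ndarray,
    spacing_mm: float,
    noise_sd_mm: float,
    seed: int,
) -> np.ndarray:
    """Emulate a human annotator's US tumor delineation.

    The true boundary is displaced by a smooth random radial field whose
    pointwise standard deviation is ``noise_sd_mm`` — the annotator
    misses fine irregular growth at low-contrast boundaries but does not
    make high-frequency errors.  The result is a single connected region
    on the same grid.
    """
    from scipy import ndimage

    mask = np.asarray(true_tumor_mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot simulate an annotation of an empty mask")
    _, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"input mask must be a single connected region, found {n}")
    if noise_sd_mm == 0.0:
        return mask.astype(np.uint8)
    grid = GridSpec(mask.shape, (spacing_mm, spacing_mm))
    contour = contour_from_mask(mask, grid)
    rng = np.random.default_rng(seed)
    perturbed = _perturb_polygon_radial(contour.vertices, noise_sd_mm, rng)
    out = rasterize_contour(
        AnnotationContour(perturbed, source="US_M", frame="US"), grid
    )
    labels, n = ndimage.label(out)
    if n > 1:  # radial clipping makes this rare; keep the dominant region
        sizes = ndimage.sum(out, labels, range(1, n + 1))
        out = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    return out


def generate_study(spec: PhantomSpec, rasterize: bool = True) -> PhantomStudy:
    """Full phantom cohort with a manifest and exclusion flags.

    A fixed fraction of slides is excluded (emulating subdivided slides
    and slides without tumor in the histopathology workflow); exclusions
    are drawn from a dedicated seeded stream so they are reproducible
    and independent of the imaging noise.
    """
    pairs, truths, rows = [], [], []
    n_total = spec.n_patients * spec.slices_per_patient
    n_excl = int(round(spec.exclusion_fraction * n_total))
    srng = _rng(spec.seed, _P_STUDY)
    excluded = set(srng.choice(n_total, size=n_excl, replace=False)) if n_excl else set()
    reasons = ("subdivided slide", "no tumor on slide")

    flat = 0
    for p in range(spec.n_patients):
        for s in range(spec.slices_per_patient):
            pair, truth = generate_specimen_slice(spec, p, s, rasterize=rasterize)
            pairs.append(pair)
            truths.append(truth)
            is_excluded = flat in excluded
            rows.append(
                {
                    "slide_id": pair.slide_id,
                    "patient_index": p,
                    "slice_index": s,
                    "included": not is_excluded,
                    "exclusion_reason": reasons[flat % 2] if is_excluded else "",
                }
            )
            flat += 1
    manifest = pd.DataFrame(
        rows, columns=["slide_id", "patient_index", "slice_index", "included", "exclusion_reason"]
    )
    return PhantomStudy(spec=spec, pairs=pairs, truths=truths, manifest=manifest)
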