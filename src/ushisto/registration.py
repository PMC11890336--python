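"""Point-list registration of an ultrasound slice to its histology slide.

The workflow mirrors the manual landmark protocol used for resected
tongue specimens: for each slice/slide pair the annotator places
circumferential landmarks along the specimen outline in both modalities
and localizes up to three fiducial cannula tracks.  Four point-list
variants are formed (circumferential only, and circumferential plus each
pair of fiducials), a transform is estimated per variant by least
squares, and each variant is scored by the target registration error
(TRE) at the fiducials withheld from estimation.  The variant with the
lowest TRE wins.

The transform maps US coordinates into the whole-slide-image (WSI)
frame; annotation transfer into the US frame therefore uses its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    FIDUCIAL_ROLES,
    ROLE_CIRCUMFERENTIAL,
    Landmark,
    SlicePair,
    Transform2D,
)

__all__ = [
    "PointListVariant",
    "RegistrationResult",
    "enumerate_point_list_variants",
    "estimate_transform",
    "target_registration_error",
    "register_slice_pair",
    "pair_landmarks",
    "fiducial_centroid",
]

LandmarkPair = tuple[Landmark, Landmark]  # (US, WSI)


@dataclass(frozen=True)
class PointListVariant:
    """One training/validation split of the landmark correspondences.

    Variant 1 trains on circumferential landmarks only and validates on
    every fiducial; the remaining variants move all but one fiducial
    into the training set and validate on the left-out one.
    """

    variant_id: int
    training_points: tuple[LandmarkPair, ...]
    validation_fiducials: tuple[LandmarkPair, ...]

    def __post_init__(self) -> None:
        if len(self.training_points) < 3:
            raise ValueError("a variant needs >= 3 training pairs")
        if len(self.validation_fiducials) < 1:
            raise ValueError("a variant needs >= 1 validation fiducial")
        train_ids = {id(p) for pair in self.training_points for p in pair}
        val_ids = {id(p) for pair in self.validation_fiducials for p in pair}
        if train_ids & val_ids:
            raise ValueError("training and validation sets must be disjoint")


@dataclass
class RegistrationResult:
    per_variant_tre_mm: dict[int, float]
    best_variant: int
    best_transform: Transform2D
    best_tre_mm: float
    variants: list[PointListVariant] = field(default_factory=list)
    per_variant_transform: dict[int, Transform2D] = field(default_factory=dict)


def _fiducials_in_order(fiducial_pairs: dict[str, LandmarkPair]) -> list[str]:
    return [r for r in FIDUCIAL_ROLES if r in fiducial_pairs]


def enumerate_point_list_variants(
    circumferential_pairs: list[LandmarkPair],
    fiducial_pairs: dict[str, LandmarkPair],
) -> list[PointListVariant]:
    """Build the point-list variants for one slice pair.

    With three fiducials this returns exactly the four variants of the
    manual protocol; with k < 3 fiducials, variant 1 plus every
    leave-one-out subset of size k-1 is returned so that each variant
    keeps at least one validation marker.

    Raises if no fiducial is available (TRE would be undefined) or if
    fewer than three circumferential pairs are given.
    """
    if len(circumferential_pairs) < 3:
        raise ValueError(
            f"need >= 3 circumferential landmark pairs, got {len(circumferential_pairs)}"
        )
    roles = _fiducials_in_order(fiducial_pairs)
    if not roles:
        raise ValueError("no validation marker available: at least one fiducial required")

    circ = tuple(circumferential_pairs)
    variants = [
        PointListVariant(
            variant_id=1,
            training_points=circ,
            validation_fiducials=tuple(fiducial_pairs[r] for r in roles),
        )
    ]
    if len(roles) >= 2:
        vid = 2
        # training subsets of size k-1, in the protocol's order:
        # (left,middle) -> validate right; (left,right) -> middle; (middle,right) -> left
        for held_out in reversed(roles):
            training_roles = [r for r in roles if r != held_out]
            variants.append(
                PointListVariant(
                    variant_id=vid,
                    training_points=circ + tuple(fiducial_pairs[r] for r in training_roles),
                    validation_fiducials=(fiducial_pairs[held_out],),
                )
            )
            vid += 1
    return variants


def _as_points(landmarks) -> np.ndarray:
    return np.array([lm.position_mm for lm in landmarks], dtype=float)


def estimate_transform(
    src_points: np.ndarray, dst_points: np.ndarray, model: str = "similarity"
) -> Transform2D:
    """Least-squares transform mapping src (US) onto dst (WSI) points.

    rigid / similarity use the closed-form SVD solution of the
    orthogonal Procrustes problem (similarity adds the optimal isotropic
    scale); affine solves the normal equations.  A data set whose best
    orthogonal fit is a reflection raises for rigid/similarity, since
    the physical slide cannot be mirrored relative to the US slice.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 point pairs, got {n}")

    if model == "affine":
        design = np.column_stack([src, np.ones(n)])
        coef, _, rank, _ = np.linalg.lstsq(design, dst, rcond=None)
        if rank < 3:
            raise np.linalg.LinAlgError(
                "affine estimation is rank-deficient (collinear points)"
            )
        m = np.eye(3)
        m[:2, :2] = coef[:2].T
        m[:2, 2] = coef[2]
        return Transform2D(m, model="affine")

    if model not in ("rigid", "similarity"):
        raise ValueError(f"unknown transform model {model!r}")

    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    src_c = src - mu_s
    dst_c = dst - mu_d
    cov = dst_c.T @ src_c / n
    u, d, vt = np.linalg.svd(cov)
    if np.linalg.det(u @ vt) < 0:
        raise ValueError(
            "point sets require a reflection; rigid/similarity transforms "
            "are restricted to det > 0"
        )
    rot = u @ vt
    if model == "similarity":
        var_s = (src_c**2).sum() / n
        scale = float(d.sum() / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * rot @ mu_s
    m = np.eye(3)
    m[:2, :2] = scale * rot
    m[:2, 2] = t
    return Transform2D(m, model=model)


def target_registration_error(
    transform: Transform2D,
    us_validation: np.ndarray,
    wsi_validation: np.ndarray,
) -> float:
    """Mean Euclidean error (mm) at validation markers.

    Each US validation marker is mapped into the WSI frame and compared
    with its counterpart:  sqrt((US_x - PA_x)^2 + (US_y - PA_y)^2).
    With several validation markers the TRE is their arithmetic mean.
    """
    us = np.atleast_2d(np.asarray(us_validation, dtype=float))
    wsi = np.atleast_2d(np.asarray(wsi_validation, dtype=float))
    if us.shape != wsi.shape or us.shape[0] < 1:
        raise ValueError("validation lists must be equal-length and non-empty")
    mapped = transform.apply(us)
    return float(np.mean(np.linalg.norm(mapped - wsi, axis=1)))


def pair_landmarks(
    us_landmarks: list[Landmark], wsi_landmarks: list[Landmark]
) -> tuple[list[LandmarkPair], dict[str, LandmarkPair]]:
    """Match landmarks across modalities.

    Circumferential landmarks correspond by label; fiducials by role.
    Landmarks present in only one modality are dropped.
    """
    circ: list[LandmarkPair] = []
    us_by_label = {lm.label: lm for lm in us_landmarks if lm.role == ROLE_CIRCUMFERENTIAL}
    for wm in wsi_landmarks:
        if wm.role == ROLE_CIRCUMFERENTIAL and wm.label in us_by_label:
            circ.append((us_by_label[wm.label], wm))
    fid: dict[str, LandmarkPair] = {}
    us_by_role = {lm.role: lm for lm in us_landmarks if lm.role in FIDUCIAL_ROLES}
    for wm in wsi_landmarks:
        if wm.role in FIDUCIAL_ROLES and wm.role in us_by_role:
            if wm.role in fid:
                raise ValueError(f"duplicate fiducial role {wm.role!r}")
            fid[wm.role] = (us_by_role[wm.role], wm)
    return circ, fid


def register_slice_pair(pair: SlicePair, model: str = "similarity") -> RegistrationResult:
    """Run the full variant enumeration and pick the lowest-TRE transform.

    Ties are broken toward the lowest variant id, which makes the result
    deterministic (and selects variant 1 in the exact, noise-free case
    where every variant achieves zero error).
    """
    circ, fid = pair_landmarks(pair.us_landmarks, pair.wsi_landmarks)
    variants = enumerate_point_list_variants(circ, fid)
    tres: dict[int, float] = {}
    transforms: dict[int, Transform2D] = {}
    for v in variants:
        src = _as_points([p[0] for p in v.training_points])
        dst = _as_points([p[1] for p in v.training_points])
        t = estimate_transform(src, dst, model=model)
        us_val = _as_points([p[0] for p in v.validation_fiducials])
        wsi_val = _as_points([p[1] for p in v.validation_fiducials])
        tres[v.variant_id] = target_registration_error(t, us_val, wsi_val)
        transforms[v.variant_id] = t
    best = min(sorted(tres), key=lambda k: tres[k])
    return RegistrationResult(
        per_variant_tre_mm=tres,
        best_variant=best,
        best_transform=transforms[best],
        best_tre_mm=tres[best],
        variants=variants,
        per_variant_transform=transforms,
    )


def fiducial_centroid(
    mask: np.ndarray, spacing_mm: tuple[float, float], origin_mm: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Physical centroid of a segmented fiducial defect.

    On the whole-slide image the cannula track can be segmented rather
    than clicked; its centre point then serves as the fiducial position.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("fiducial mask is empty")
    r, c = ndimage.center_of_mass(mask)
    sx, sy = spacing_mm
    return (origin_mm[0] + (c + 0.5) * sx, origin_mm[1] + (r + 0.5) * sy)
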