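"""Landmark-based planar registration of section images to the atlas.

Coronal sections are aligned to the reference atlas with a 5-parameter planar
transform: rotation, *independent* scale factors along the mediolateral and
dorsoventral axes (histological sectioning compresses tissue anisotropically),
and translation.  The mapping is

    p_atlas = S . R(theta) . p_image + t,      S = diag(s_ml, s_dv)

with points written as (x, y) = (mediolateral column, dorsoventral row).
Rotation is applied first, then anisotropic scaling in the atlas axis frame,
then translation; fixing this order makes the parameters identifiable.

Fitting minimizes the sum of squared atlas-frame distances between mapped
image landmarks and their atlas counterparts.  A closed-form similarity
(Procrustes) fit provides the starting point and Gauss–Newton refines the
five parameters; the anisotropic problem has no closed form.

Detection runs on raw images and detected coordinates are transformed as
points, so quantification never depends on image resampling; the image
resampling path (inverse mapping + bilinear interpolation) exists for visual
inspection of the registration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LandmarkSet",
    "PlanarTransform",
    "FitReport",
    "DegenerateLandmarksError",
    "fit_transform",
    "apply_transform",
    "apply_transform_image",
    "manual_adjust",
    "load_landmarks",
    "save_transforms",
    "load_transforms",
]


class DegenerateLandmarksError(ValueError):
    """Fewer than 3 pairs, or collinear image points."""


@dataclass(frozen=True)
class LandmarkSet:
    """Index-aligned (image point, atlas point) pairs for one section."""

    image_points: np.ndarray  # (n, 2) image-frame pixels, columns (x, y)
    atlas_points: np.ndarray  # (n, 2) atlas-frame pixels
    section_index: int = 0

    def __post_init__(self) -> None:
        ip = np.asarray(self.image_points, dtype=float)
        ap = np.asarray(self.atlas_points, dtype=float)
        if ip.shape != ap.shape or ip.ndim != 2 or ip.shape[1] != 2:
            raise ValueError("image and atlas points must be matching (n, 2) arrays")
        object.__setattr__(self, "image_points", ip)
        object.__setattr__(self, "atlas_points", ap)

    def __len__(self) -> int:
        return self.image_points.shape[0]


@dataclass(frozen=True)
class PlanarTransform:
    """Rotation -> anisotropic scale -> translation, image frame to atlas frame.

    Attributes
    ----------
    theta:
        Rotation angle in radians (counter-clockwise in (x, y)).
    s_ml, s_dv:
        Scale factors along the atlas mediolateral (x) and dorsoventral (y)
        axes; both strictly positive (reflections are disallowed — sections
        flipped at acquisition must be pre-flipped explicitly).
    tx, ty:
        Translation in atlas pixels.
    """

    theta: float = 0.0
    s_ml: float = 1.0
    s_dv: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not (self.s_ml > 0 and self.s_dv > 0):
            raise ValueError(
                f"scales must be positive, got s_ml={self.s_ml}, s_dv={self.s_dv}"
            )

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part S @ R(theta)."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[self.s_ml * c, -self.s_ml * s], [self.s_dv * s, self.s_dv * c]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def params(self) -> np.ndarray:
        return np.array([self.theta, self.s_ml, self.s_dv, self.tx, self.ty])

    def inverse(self) -> "PlanarTransform":
        """Inverse mapping, returned as an affine-equivalent callable pair.

        The inverse of rotation-then-anisotropic-scale is not of the same
        5-parameter form in general, so the inverse is exposed through
        :func:`apply_transform` with ``inverse=True`` rather than as a
        ``PlanarTransform``.
        """
        raise NotImplementedError("use apply_transform(..., inverse=True)")


def apply_transform(
    transform: PlanarTransform, points: np.ndarray, inverse: bool = False
) -> np.ndarray:
    """Map (n, 2) points (or a single (2,) point) through the transform.

    With ``inverse=True`` maps atlas-frame points back to the image frame
    (exact inverse of the forward affine map).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    A, t = transform.matrix, transform.translation
    if inverse:
        out = (pts - t) @ np.linalg.inv(A).T
    else:
        out = pts @ A.T + t
    return out[0] if single else out


def apply_transform_image(
    transform: PlanarTransform,
    image: np.ndarray,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample an image onto the atlas grid by inverse mapping.

    Each atlas pixel (x, y) is pulled from the image at the inverse-mapped
    location with bilinear interpolation; out-of-field pixels are 0.
    """
    image = np.asarray(image, dtype=float)
    h, w = out_shape if out_shape is not None else image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    atlas_pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    img_pts = apply_transform(transform, atlas_pts, inverse=True)
    # map_coordinates indexes (row, col) = (y, x)
    coords = np.vstack([img_pts[:, 1], img_pts[:, 0]])
    out = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
    return out.reshape(h, w)


def manual_adjust(
    transform: PlanarTransform,
    d_theta: float = 0.0,
    d_s_ml: float = 0.0,
    d_s_dv: float = 0.0,
    d_tx: float = 0.0,
    d_ty: float = 0.0,
    log: list | None = None,
) -> PlanarTransform:
    """Apply additive parameter increments, rejecting non-positive scales.

    The input transform is unchanged; the adjustment is appended to ``log``
    when given (the audit trail for post-hoc alignment touch-ups).
    """
    new_s_ml = transform.s_ml + d_s_ml
    new_s_dv = transform.s_dv + d_s_dv
    if new_s_ml <= 0 or new_s_dv <= 0:
        raise ValueError(
            f"adjustment would drive a scale non-positive "
            f"(s_ml -> {new_s_ml}, s_dv -> {new_s_dv})"
        )
    adjusted = replace(
        transform,
        theta=transform.theta + d_theta,
        s_ml=new_s_ml,
        s_dv=new_s_dv,
        tx=transform.tx + d_tx,
        ty=transform.ty + d_ty,
    )
    if log is not None:
        log.append(
            {
                "d_theta": d_theta,
                "d_s_ml": d_s_ml,
                "d_s_dv": d_s_dv,
                "d_tx": d_tx,
                "d_ty": d_ty,
            }
        )
    return adjusted


@dataclass(frozen=True)
class FitReport:
    residuals: np.ndarray  # per-pair atlas-frame distances
    rms: float
    n_iter: int
    converged: bool


def _similarity_fit(src: np.ndarray, dst: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Least-squares similarity (rotation + uniform scale + translation).

    Umeyama closed form without reflection; used to initialize the
    anisotropic fit and as the constrained baseline for the monotonicity
    property (anisotropic RMS <= similarity RMS).
    """
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U @ Vt) < 0:
        S[1, 1] = -1
    R = U @ S @ Vt
    var_s = (sc**2).sum() / len(src)
    scale = float(np.trace(np.diag(D) @ S) / var_s) if var_s > 0 else 1.0
    scale = max(scale, 1e-12)
    theta = math.atan2(R[1, 0], R[0, 0])
    t = mu_d - scale * (R @ mu_s)
    return theta, scale, t


def fit_transform(
    landmarks: LandmarkSet,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[PlanarTransform, FitReport]:
    """Least-squares fit of the 5-parameter planar transform.

    Minimizes ``sum_i || S R p_i + t - q_i ||^2`` over (theta, s_ml, s_dv,
    tx, ty) by Gauss–Newton from a closed-form similarity start; convergence
    when the step's infinity norm drops below ``tol`` or after ``max_iter``
    iterations.

    Returns the fitted transform and a :class:`FitReport` with per-pair
    residual distances and their RMS (``sqrt(mean ||r_i||^2)`` over pairs).
    """
    src = landmarks.image_points
    dst = landmarks.atlas_points
    n = len(landmarks)
    if n < 3:
        raise DegenerateLandmarksError(f"need >= 3 landmark pairs, got {n}")
    centered = src - src.mean(axis=0)
    # Collinearity: rank of the centered point cloud.
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateLandmarksError("image points are collinear")

    theta0, scale0, t0 = _similarity_fit(src, dst)
    p = np.array([theta0, scale0, scale0, t0[0], t0[1]])

    def residual_vec(params: np.ndarray) -> np.ndarray:
        th, sml, sdv, tx, ty = params
        c, s = math.cos(th), math.sin(th)
        rx = src[:, 0] * c - src[:, 1] * s
        ry = src[:, 0] * s + src[:, 1] * c
        ex = sml * rx + tx - dst[:, 0]
        ey = sdv * ry + ty - dst[:, 1]
        return np.concatenate([ex, ey]), (rx, ry, c, s)

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        r, (rx, ry, c, s) = residual_vec(p)
        th, sml, sdv = p[0], p[1], p[2]
        # Jacobian of (ex, ey) wrt (theta, s_ml, s_dv, tx, ty)
        J = np.zeros((2 * len(src), 5))
        J[: len(src), 0] = sml * (-src[:, 0] * s - src[:, 1] * c)
        J[len(src):, 0] = sdv * (src[:, 0] * c - src[:, 1] * s)
        J[: len(src), 1] = rx
        J[len(src):, 2] = ry
        J[: len(src), 3] = 1.0
        J[len(src):, 4] = 1.0
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        p = p + step
        # keep scales positive during iteration
        p[1] = max(p[1], 1e-9)
        p[2] = max(p[2], 1e-9)
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    transform = PlanarTransform(theta=p[0], s_ml=p[1], s_dv=p[2], tx=p[3], ty=p[4])
    mapped = apply_transform(transform, src)
    dists = np.linalg.norm(mapped - dst, axis=1)
    rms = float(np.sqrt(np.mean(dists**2)))
    return transform, FitReport(residuals=dists, rms=rms, n_iter=n_iter, converged=converged)


def fit_similarity(landmarks: LandmarkSet) -> tuple[PlanarTransform, FitReport]:
    """Constrained fit with s_ml = s_dv (rotation + uniform scale + shift)."""
    if len(landmarks) < 3:
        raise DegenerateLandmarksError(f"need >= 3 landmark pairs, got {len(landmarks)}")
    theta, scale, t = _similarity_fit(landmarks.image_points, landmarks.atlas_points)
    tr = PlanarTransform(theta=theta, s_ml=scale, s_dv=scale, tx=t[0], ty=t[1])
    mapped = apply_transform(tr, landmarks.image_points)
    dists = np.linalg.norm(mapped - landmarks.atlas_points, axis=1)
    return tr, FitReport(dists, float(np.sqrt(np.mean(dists**2))), 0, True)


# -- I/O -------------------------------------------------------------------

def load_landmarks(path: str | Path) -> dict[int, LandmarkSet]:
    """Read a landmark CSV (section_index, ix, iy, ax, ay) into per-section sets."""
    df = pd.read_csv(path)
    out: dict[int, LandmarkSet] = {}
    for sec, grp in df.groupby("section_index"):
        out[int(sec)] = LandmarkSet(
            image_points=grp[["ix", "iy"]].to_numpy(float),
            atlas_points=grp[["ax", "ay"]].to_numpy(float),
            section_index=int(sec),
        )
    return out


def save_landmarks(landmarks: dict[int, LandmarkSet], path: str | Path) -> None:
    rows = []
    for sec in sorted(landmarks):
        lm = landmarks[sec]
        for (ix, iy), (ax, ay) in zip(lm.image_points, lm.atlas_points):
            rows.append({"section_index": sec, "ix": ix, "iy": iy, "ax": ax, "ay": ay})
    pd.DataFrame(rows).to_csv(path, index=False)


def save_transforms(
    transforms: dict[int, PlanarTransform],
    path: str | Path,
    rms: dict[int, float] | None = None,
) -> None:
    recs = [
        {
            "section_index": sec,
            "theta_rad": tr.theta,
            "s_ml": tr.s_ml,
            "s_dv": tr.s_dv,
            "tx": tr.tx,
            "ty": tr.ty,
            "rms": None if rms is None else rms.get(sec),
        }
        for sec, tr in sorted(transforms.items())
    ]
    Path(path).write_text(json.dumps(recs, indent=1, sort_keys=True))


def load_transforms(path: str | Path) -> dict[int, PlanarTransform]:
    recs = json.loads(Path(path).read_text())
    return {
        int(r["section_index"]): PlanarTransform(
            theta=r["theta_rad"], s_ml=r["s_ml"], s_dv=r["s_dv"], tx=r["tx"], ty=r["ty"]
        )
        for r in recs
    }
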