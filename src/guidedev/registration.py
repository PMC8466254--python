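"""Point-based rigid registration of cast space to CBCT space.

The cast-to-CBCT superimposition is a least-squares absolute-orientation
problem: given paired landmark points (operator-picked dental-surface points
or radiopaque fiducial markers), find the proper rigid transform minimizing
the sum of squared residuals.  The closed-form SVD (Kabsch) solution is used:
subtract centroids, form the cross-covariance, take its SVD, and correct the
determinant so no reflection is ever returned.

Diagnostics follow the standard fiducial-error vocabulary: FRE (fiducial
registration error, the post-fit RMS residual) and, in simulation where the
true transform is known, TRE (target registration error, the displacement the
estimated transform induces at a point of interest relative to the truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import IllPosedRegistrationError
from .geometry import Implant, RigidTransform, decompose_deviation

__all__ = [
    "PointCorrespondences",
    "RegistrationResult",
    "rigid_point_register",
    "apply_transform",
    "target_registration_error",
    "lateral_axial_tre",
]

# Collinear (or coincident) sources leave a rotation about the line free;
# detected via the singular-value spread of the centered configuration.
_COLLINEARITY_RTOL = 1e-8


@dataclass(frozen=True)
class PointCorrespondences:
    """Paired landmarks: source in cast space, target in CBCT space."""

    source_points: np.ndarray
    target_points: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.source_points, dtype=float))
        t = np.atleast_2d(np.asarray(self.target_points, dtype=float))
        if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
            raise IllPosedRegistrationError(
                f"source/target must be matching (n, 3) arrays, got {s.shape} vs {t.shape}"
            )
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(t))):
            raise IllPosedRegistrationError("non-finite coordinates in correspondences")
        if self.labels is not None and len(self.labels) != len(s):
            raise IllPosedRegistrationError("labels length must match point count")
        object.__setattr__(self, "source_points", s)
        object.__setattr__(self, "target_points", t)

    def __len__(self) -> int:
        return len(self.source_points)


@dataclass(frozen=True)
class RegistrationResult:
    """Fitted transform with its residual diagnostics."""

    transform: RigidTransform
    fre_rms_mm: float
    per_point_residuals_mm: np.ndarray = field(repr=False)


def rigid_point_register(corr: PointCorrespondences) -> RegistrationResult:
    """Least-squares rigid fit of source points onto target points.

    Solves min_{R,t} sum_i ||R s_i + t - t_i||^2 over proper rotations with
    equal weights.  Requires at least three non-collinear correspondences;
    otherwise the rotation is not identifiable and an
    :class:`~guidedev.errors.IllPosedRegistrationError` is raised.
    """
    src, tgt = corr.source_points, corr.target_points
    n = len(src)
    if n < 3:
        raise IllPosedRegistrationError(f"need at least 3 correspondences, got {n}")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)

    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] < _COLLINEARITY_RTOL * max(sv[0], 1.0):
        raise IllPosedRegistrationError(
            "source points are collinear: rotation about the line is unconstrained"
        )

    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)

    transform = RigidTransform(R, t)
    residuals = np.linalg.norm(transform.apply(src) - tgt, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(transform=transform, fre_rms_mm=fre, per_point_residuals_mm=residuals)


def apply_transform(transform: RigidTransform, obj):
    """Apply a rigid transform to points (any (..., 3) array) or an Implant."""
    if isinstance(obj, Implant):
        return transform.apply_implant(obj)
    return transform.apply(obj)


def target_registration_error(
    result: RegistrationResult | RigidTransform,
    true_transform: RigidTransform,
    target,
) -> float:
    """Distance between estimated and true mappings of ``target``, in mm.

    A simulation diagnostic: measures how far the estimated transform places
    a point of interest (e.g. an implant center) from where the true
    transform places it.
    """
    est = result.transform if isinstance(result, RegistrationResult) else result
    return float(np.linalg.norm(est.apply(target) - true_transform.apply(target)))


def lateral_axial_tre(
    result: RegistrationResult | RigidTransform,
    true_transform: RigidTransform,
    planned: Implant,
    at: str = "platform",
):
    """Resolve the TRE displacement at an implant center against its axis.

    The displacement (estimated minus true mapping) at the platform or apex
    center is decomposed into a lateral component (perpendicular to the
    planned axis, the direction clinically exposed to buccal-lingual
    registration error) and a signed axial component.  The decomposition uses
    the planned implant mapped into target (CBCT) space by the true
    transform, so the components are expressed in the frame the deviations
    are measured in.  Returns ``(lateral_mm, axial_mm)``.
    """
    if at not in ("platform", "apex"):
        raise ValueError(f"'at' must be 'platform' or 'apex', got {at!r}")
    est = result.transform if isinstance(result, RegistrationResult) else result
    planned_cbct = true_transform.apply_implant(planned)
    center = getattr(planned, at)
    return decompose_deviation(planned_cbct, true_transform.apply(center), est.apply(center))
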