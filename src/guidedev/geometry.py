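"""Implant geometry and planned-vs-placed deviation metrics.

An implant fixture is reduced to its two defining points — the platform
(coronal) center and the apex (apical) center — in one fixed right-handed
patient coordinate frame, in millimetres.  Between a planned and a placed
fixture six accuracy measures are computed, the standard outcome set for
guided implant surgery:

* global deviation at platform and apex: 3D Euclidean distance between the
  corresponding centers;
* lateral deviation at platform and apex: component of the center-to-center
  displacement perpendicular to the *planned* implant axis;
* depth deviation: signed component of the platform displacement along the
  planned axis (positive = placed deeper, i.e. toward the apex);
* angular deviation: 3D angle between the two platform-to-apex axes.

With this decomposition convention ``global**2 == lateral**2 + depth**2``
holds exactly at the platform, and all metrics are invariant under a common
rigid motion of both fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigError, InvalidGeometryError

__all__ = [
    "Implant",
    "RigidTransform",
    "DeviationRecord",
    "implant_axis",
    "global_deviation",
    "decompose_deviation",
    "angular_deviation",
    "measure_deviations",
    "safety_flags",
    "as_point",
]

#: Column order used by every deviation table in the package.
METRIC_COLUMNS = (
    "global_platform_mm",
    "lateral_platform_mm",
    "global_apex_mm",
    "lateral_apex_mm",
    "depth_mm",
    "angular_deg",
)


def as_point(p) -> np.ndarray:
    """Coerce to a finite float64 3-vector (mm)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise InvalidGeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidGeometryError(f"non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class Implant:
    """An implant fixture: platform center, apex center, and factor labels.

    ``factors`` carries the categorical covariates of the study design
    (registration_method, jaw, guide_support, site, bone_quality, ...).
    """

    platform: np.ndarray
    apex: np.ndarray
    id: str = ""
    factors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "platform", as_point(self.platform))
        object.__setattr__(self, "apex", as_point(self.apex))
        if self.length_mm <= 0.0:
            raise InvalidGeometryError(
                f"implant {self.id!r}: platform and apex coincide"
            )

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.apex - self.platform))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidGeometryError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidGeometryError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InvalidGeometryError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other, i.e. apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_implant(self, implant: Implant) -> Implant:
        return replace(
            implant,
            platform=self.apply(implant.platform),
            apex=self.apply(implant.apex),
        )


@dataclass(frozen=True)
class DeviationRecord:
    """One implant's accuracy row: the six metrics plus factor labels.

    ``depth_mm`` is signed (positive = deeper than planned); use
    :meth:`absolute` for the reporting convention in which depth is folded
    to its magnitude.
    """

    global_platform_mm: float
    lateral_platform_mm: float
    global_apex_mm: float
    lateral_apex_mm: float
    depth_mm: float
    angular_deg: float
    factors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in METRIC_COLUMNS[:4]:
            if getattr(self, name) < 0:
                raise InvalidGeometryError(f"{name} must be nonnegative")
        if not (0.0 <= self.angular_deg <= 180.0):
            raise InvalidGeometryError("angular_deg must lie in [0, 180]")

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_COLUMNS}
        d.update(self.factors)
        return d

    def absolute(self) -> "DeviationRecord":
        """Copy with depth folded to |depth| (table reporting convention)."""
        return replace(self, depth_mm=abs(self.depth_mm))


def implant_axis(implant: Implant) -> np.ndarray:
    """Unit axis of the fixture, oriented platform -> apex."""
    d = implant.apex - implant.platform
    n = np.linalg.norm(d)
    if n <= 0.0:
        raise InvalidGeometryError("degenerate implant: zero length")
    return d / n


def global_deviation(planned_center, placed_center) -> float:
    """3D Euclidean distance between corresponding centers, in mm."""
    return float(np.linalg.norm(as_point(placed_center) - as_point(planned_center)))


def decompose_deviation(planned: Implant, planned_center, placed_center):
    """Split a center displacement into lateral and signed axial parts.

    The displacement ``placed_center - planned_center`` is resolved against
    the planned implant axis: the axial part is the signed projection
    (positive toward the apex, i.e. deeper), the lateral part the norm of the
    perpendicular remainder.  Returns ``(lateral_mm, axial_mm_signed)``.
    """
    a = implant_axis(planned)
    d = as_point(placed_center) - as_point(planned_center)
    axial = float(d @ a)
    lateral = float(np.linalg.norm(d - axial * a))
    return lateral, axial


def angular_deviation(planned: Implant, placed: Implant) -> float:
    """3D angle between the planned and placed implant axes, in degrees."""
    cosang = float(implant_axis(planned) @ implant_axis(placed))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_deviations(planned: Implant, placed: Implant) -> DeviationRecord:
    """All six deviation metrics between a planned and a placed fixture.

    Factor labels are copied from the planned implant, which is the record
    that carries the study covariates.
    """
    lat_p, depth = decompose_deviation(planned, planned.platform, placed.platform)
    lat_a, _ = decompose_deviation(planned, planned.apex, placed.apex)
    return DeviationRecord(
        global_platform_mm=global_deviation(planned.platform, placed.platform),
        lateral_platform_mm=lat_p,
        global_apex_mm=global_deviation(planned.apex, placed.apex),
        lateral_apex_mm=lat_a,
        depth_mm=depth,
        angular_deg=angular_deviation(planned, placed),
        factors=dict(planned.factors),
    )


#: Consensus planning margins (mm): overall safety margin, and the
#: horizontal / vertical mean system-error bounds to report against.
DEFAULT_SAFETY_MARGIN_MM = 2.0
HORIZONTAL_BOUND_MM = 1.2
VERTICAL_BOUND_MM = 0.5


def safety_flags(
    record: DeviationRecord,
    lateral_margin_mm: float = DEFAULT_SAFETY_MARGIN_MM,
    depth_margin_mm: float = DEFAULT_SAFETY_MARGIN_MM,
) -> dict:
    """Flag metrics that exceed planning safety margins (strict >).

    Returns a dict of booleans: one flag per distance metric against the
    given margins, plus ``lateral_platform_system`` / ``lateral_apex_system``
    against the 1.2 mm horizontal bound and ``depth_system`` against the
    0.5 mm vertical bound.
    """
    if lateral_margin_mm <= 0 or depth_margin_mm <= 0:
        raise ConfigError("safety margins must be positive")
    return {
        "global_platform": record.global_platform_mm > lateral_margin_mm,
        "lateral_platform": record.lateral_platform_mm > lateral_margin_mm,
        "global_apex": record.global_apex_mm > lateral_margin_mm,
        "lateral_apex": record.lateral_apex_mm > lateral_margin_mm,
        "depth": abs(record.depth_mm) > depth_margin_mm,
        "lateral_platform_system": record.lateral_platform_mm > HORIZONTAL_BOUND_MM,
        "lateral_apex_system": record.lateral_apex_mm > HORIZONTAL_BOUND_MM,
        "depth_system": abs(record.depth_mm) > VERTICAL_BOUND_MM,
    }
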