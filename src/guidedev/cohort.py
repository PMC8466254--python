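"""Synthetic cohort generation for guided-implant accuracy studies.

No raw data from clinical accuracy trials of this kind are public (CBCT
volumes and scanned casts are identifiable), so the statistical pipeline is
exercised on a declared surrogate with the same error structure:

* a parabolic dental arch carrying surface landmark points (with recorded
  outward buccal-lingual normals) and off-arch fiducial marker positions on
  a radiographic-template surrogate;
* a true cast-to-CBCT rigid transform (small rotation, moderate translation);
* CBCT-side landmark localization noise — isotropic Gaussian for fiducial
  markers, anisotropic for dental-surface points with the standard deviation
  inflated along the buccal-lingual normal, emulating metal-streak artifacts
  that smear tooth surfaces in that direction;
* guide mechanical error at placement — lateral offset, depth offset, and a
  tilt about a random perpendicular axis, emulating sleeve tolerance and
  guide flexure (larger for distal-extension guides);
* the unbalanced three-factor layout of the study design
  (registration method x jaw x guide support).

Every draw flows from one recorded seed; identical seeds give identical
cohorts.  All distributions are surrogates, not claims about the clinical
data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import (
    METRIC_COLUMNS,
    DeviationRecord,
    Implant,
    RigidTransform,
    measure_deviations,
)
from .registration import PointCorrespondences, rigid_point_register

__all__ = [
    "ScenarioConfig",
    "CohortDesign",
    "GroupEffects",
    "Scenario",
    "generate_scenario",
    "corrupt_correspondences",
    "simulate_placement",
    "generate_cohort",
    "cohort_frame",
    "table_design",
]

FACTOR_COLUMNS = ("registration_method", "jaw", "guide_support")

REGISTRATION_METHODS = ("dental_surface", "fiducial_marker")
JAWS = ("maxilla", "mandible")
GUIDE_SUPPORTS = ("mucosa", "bilateral_tooth", "distal_extension")


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry and noise parameters of one simulated patient scenario.

    Units: mm for lengths and sigmas, degrees for angles.  The artifact
    inflation multiplies the surface-point noise SD along each point's
    buccal-lingual normal; in-plane surface noise keeps ``surface_sigma_mm``.
    """

    n_surface_points: int = 5
    n_fiducials: int = 4
    arch_radius_mm: float = 25.0
    marker_sigma_mm: float = 0.1
    surface_sigma_mm: float = 0.1
    artifact_inflation: float = 3.0
    guide_lateral_sigma_mm: float = 0.3
    guide_angle_sigma_deg: float = 1.5
    guide_depth_sigma_mm: float = 0.4
    implant_length_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "marker_sigma_mm",
            "surface_sigma_mm",
            "guide_lateral_sigma_mm",
            "guide_angle_sigma_deg",
            "guide_depth_sigma_mm",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.artifact_inflation < 1.0:
            raise ConfigError("artifact_inflation must be >= 1")
        if self.n_fiducials < 3:
            raise ConfigError("n_fiducials must be >= 3 (registration needs 3 points)")
        if self.n_surface_points < 3:
            raise ConfigError("n_surface_points must be >= 3")
        if self.arch_radius_mm <= 0 or self.implant_length_mm <= 0:
            raise ConfigError("arch_radius_mm and implant_length_mm must be > 0")


@dataclass(frozen=True)
class Scenario:
    """True (noise-free) geometry of one simulated patient, in cast space."""

    surface_points: np.ndarray     # (n, 3), on the arch at the occlusal plane
    surface_normals: np.ndarray    # (n, 3) unit outward buccal-lingual normals
    fiducial_points: np.ndarray    # (m, 3), on the template off the arch
    true_transform: RigidTransform  # cast -> CBCT
    planned_implants: tuple        # Implant objects, cast space
    config: ScenarioConfig


def _arch_curve(radius: float, u: np.ndarray):
    """Parabolic arch in the occlusal plane with outward in-plane normals.

    Parametrized by u in [-1, 1]; apex of the arch (front teeth) at u = 0.
    """
    pts = np.column_stack([radius * u, radius * (1.0 - u**2), np.zeros_like(u)])
    tangents = np.column_stack([np.full_like(u, radius), -2.0 * radius * u, np.zeros_like(u)])
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0], np.zeros_like(u)])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return pts, normals


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    return _axis_angle_rotation(axis, angle)


def _axis_angle_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


# Implant sites spread over the arch (posterior left .. posterior right).
_SITE_PARAMS = (-0.7, -0.45, -0.2, 0.2, 0.45, 0.7)


def generate_scenario(config: ScenarioConfig, rng: np.random.Generator | None = None) -> Scenario:
    """Build one patient scenario: arch landmarks, true transform, planned implants.

    Surface points sit on the arch at the occlusal plane with their outward
    buccal-lingual normals recorded; fiducials sit on a template surrogate,
    4 mm outside the arch and 4 mm above the occlusal plane.  The true
    cast-to-CBCT transform is a seeded rotation of at most 5 degrees and a
    translation of at most 10 mm per axis.  Planned implants are placed at
    fixed arch sites with axes within 5 degrees of the occlusal direction.
    Fully reproducible from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.arch_radius_mm

    u_surf = np.linspace(-0.8, 0.8, config.n_surface_points)
    surf_pts, surf_nrm = _arch_curve(R, u_surf)

    u_fid = np.linspace(-0.9, 0.9, config.n_fiducials)
    fid_on_arch, fid_nrm = _arch_curve(R, u_fid)
    fid_pts = fid_on_arch + 4.0 * fid_nrm + np.array([0.0, 0.0, 4.0])

    rot = _random_rotation(rng, max_angle_deg=5.0)
    trans = rng.uniform(-10.0, 10.0, size=3)
    true_transform = RigidTransform(rot, trans)

    implants = []
    site_pts, site_nrm = _arch_curve(R, np.asarray(_SITE_PARAMS))
    for i, (p, n) in enumerate(zip(site_pts, site_nrm)):
        # axis near the occlusal direction (-z), small seeded tilt
        tilt_axis = np.array([n[0], n[1], 0.0])
        tilt_axis /= np.linalg.norm(tilt_axis)
        tilt = _axis_angle_rotation(tilt_axis, np.radians(rng.uniform(0.0, 5.0)))
        axis = tilt @ np.array([0.0, 0.0, -1.0])
        implants.append(
            Implant(
                platform=p,
                apex=p + config.implant_length_mm * axis,
                id=f"site{i + 1}",
            )
        )
    return Scenario(
        surface_points=surf_pts,
        surface_normals=surf_nrm,
        fiducial_points=fid_pts,
        true_transform=true_transform,
        planned_implants=tuple(implants),
        config=config,
    )


def corrupt_correspondences(
    scenario: Scenario,
    mode: str,
    config: ScenarioConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PointCorrespondences:
    """Noisy registration landmarks for one of the two matching protocols.

    Source (cast-side) points are noise-free — desktop model scans are an
    order of magnitude more precise than CBCT.  Target (CBCT-side) points
    are the truly transformed sources plus localization noise:

    * ``fiducial_marker``: isotropic Gaussian, SD ``marker_sigma_mm``;
    * ``dental_surface``: anisotropic Gaussian, SD ``surface_sigma_mm``
      in-plane and ``surface_sigma_mm * artifact_inflation`` along each
      point's buccal-lingual normal (mapped to CBCT space), the streak-
      artifact surrogate.
    """
    if config is None:
        config = scenario.config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = scenario.true_transform

    if mode == "fiducial_marker":
        src = scenario.fiducial_points
        noise = rng.normal(0.0, config.marker_sigma_mm, size=src.shape)
        labels = ["fiducial"] * len(src)
    elif mode == "dental_surface":
        src = scenario.surface_points
        normals_cbct = scenario.surface_normals @ T.rotation.T
        sigma = config.surface_sigma_mm
        iso = rng.normal(0.0, sigma, size=src.shape)
        # replace the component along the buccal-lingual normal by an
        # inflated draw: in-plane SD sigma, along-normal SD sigma*inflation
        along = rng.normal(0.0, sigma * config.artifact_inflation, size=len(src))
        iso -= (np.sum(iso * normals_cbct, axis=1))[:, None] * normals_cbct
        noise = iso + along[:, None] * normals_cbct
        labels = ["surface"] * len(src)
    else:
        raise ConfigError(
            f"unknown registration mode {mode!r}; expected one of {REGISTRATION_METHODS}"
        )
    return PointCorrespondences(
        source_points=src, target_points=T.apply(src) + noise, labels=labels
    )


def simulate_placement(
    planned: Implant,
    reg_error: tuple,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    guide_sigma_scale: float = 1.0,
) -> Implant:
    """Simulate the placed implant in CBCT space for a planned fixture.

    ``reg_error`` is ``(estimated, true)`` cast-to-CBCT transforms.  The
    planned implant (cast space) is first mapped through the *estimated*
    transform — i.e. displaced from its true position by the TRE field at
    platform and apex, preserving the angular component of misregistration —
    then perturbed by the guide mechanical error: a lateral offset drawn
    isotropically in the plane perpendicular to the implant axis
    (SD ``guide_lateral_sigma_mm`` per axis), a depth offset along the axis
    (SD ``guide_depth_sigma_mm``), and a tilt about a random perpendicular
    axis through the platform (SD ``guide_angle_sigma_deg``).
    ``guide_sigma_scale`` multiplies all three guide SDs (distal-extension
    support effect).
    """
    estimated, true = reg_error
    if rng is None:
        rng = np.random.default_rng(config.seed)

    displaced = estimated.apply_implant(planned)
    axis = (displaced.apex - displaced.platform) / displaced.length_mm

    # orthonormal frame perpendicular to the implant axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    s = guide_sigma_scale
    lat = rng.normal(0.0, s * config.guide_lateral_sigma_mm, size=2)
    depth = rng.normal(0.0, s * config.guide_depth_sigma_mm)
    platform = displaced.platform + lat[0] * e1 + lat[1] * e2 + depth * axis

    phi = rng.uniform(0.0, 2.0 * np.pi)
    tilt_axis = np.cos(phi) * e1 + np.sin(phi) * e2
    tilt = np.radians(rng.normal(0.0, s * config.guide_angle_sigma_deg))
    new_axis = _axis_angle_rotation(tilt_axis, tilt) @ axis

    return replace(
        planned,
        platform=platform,
        apex=platform + planned.length_mm * new_axis,
    )


@dataclass(frozen=True)
class GroupEffects:
    """How the study factors modulate the simulated error sources.

    Defaults encode the contrasts the analysis is meant to recover:

    * the dental-surface group registers on artifact-inflated surface
      landmarks (``surface_sigma_scale`` additionally scales its surface
      noise SD) while the fiducial group registers on isotropic markers;
    * maxillary guides and distal-extension guides are mechanically less
      stable, so their guide sigmas are multiplied up.

    ``GroupEffects.null()`` switches every contrast off: both registration
    groups then use the identical isotropic marker-noise process and all
    multipliers are 1, which is the configuration used for type-I-error
    calibration.
    """

    surface_mode_for_dental_surface: bool = True
    surface_sigma_scale: float = 4.1
    maxilla_guide_scale: float = 1.95
    distal_extension_guide_scale: float = 1.9

    @classmethod
    def null(cls) -> "GroupEffects":
        return cls(
            surface_mode_for_dental_surface=False,
            surface_sigma_scale=1.0,
            maxilla_guide_scale=1.0,
            distal_extension_guide_scale=1.0,
        )


@dataclass(frozen=True)
class CohortDesign:
    """Per-cell implant counts over registration method x jaw x guide support."""

    cells: Mapping[tuple, int]
    extra_factors: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for key, count in self.cells.items():
            if len(key) != 3:
                raise ConfigError(f"cell key must be (registration, jaw, support): {key}")
            reg, jaw, sup = key
            if reg not in REGISTRATION_METHODS or jaw not in JAWS or sup not in GUIDE_SUPPORTS:
                raise ConfigError(f"unknown factor level in cell {key}")
            if count < 0:
                raise ConfigError("cell counts must be >= 0")
        if self.total == 0:
            raise ConfigError("design is empty: total implant count must be > 0")

    @property
    def total(self) -> int:
        return int(sum(self.cells.values()))

    def margin(self, factor_index: int) -> dict:
        out: dict = {}
        for key, count in self.cells.items():
            out[key[factor_index]] = out.get(key[factor_index], 0) + count
        return out


def table_design() -> CohortDesign:
    """The study's fully guided design: 56 implants with margins
    21/35 (dental surface / fiducial marker), 23/33 (maxilla / mandible),
    28/20/8 (mucosa / bilateral tooth / distal extension)."""
    cells = {
        ("dental_surface", "maxilla", "mucosa"): 5,
        ("dental_surface", "maxilla", "bilateral_tooth"): 3,
        ("dental_surface", "maxilla", "distal_extension"): 1,
        ("dental_surface", "mandible", "mucosa"): 5,
        ("dental_surface", "mandible", "bilateral_tooth"): 5,
        ("dental_surface", "mandible", "distal_extension"): 2,
        ("fiducial_marker", "maxilla", "mucosa"): 7,
        ("fiducial_marker", "maxilla", "bilateral_tooth"): 5,
        ("fiducial_marker", "maxilla", "distal_extension"): 2,
        ("fiducial_marker", "mandible", "mucosa"): 11,
        ("fiducial_marker", "mandible", "bilateral_tooth"): 7,
        ("fiducial_marker", "mandible", "distal_extension"): 3,
    }
    return CohortDesign(cells=cells)


def cohort_frame(records) -> pd.DataFrame:
    """DeviationRecords -> tidy DataFrame (metric columns then factors)."""
    rows = [r.as_dict() for r in records]
    frame = pd.DataFrame(rows)
    ordered = [c for c in METRIC_COLUMNS if c in frame.columns]
    ordered += [c for c in frame.columns if c not in ordered]
    return frame[ordered]


def generate_cohort(
    design: CohortDesign,
    config: ScenarioConfig,
    effects: GroupEffects | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one cohort of implants and return its deviation table.

    Each implant is treated as an independent observation (its own
    registration-noise and guide-error draws), mirroring the analysis
    assumption that implants are independent.  Per implant:

    1. draw noisy registration landmarks for its group's protocol and fit
       the rigid transform;
    2. place the implant through the estimated transform plus guide
       mechanical error (guide sigmas scaled by jaw / support effects);
    3. measure the six deviations against the truly transformed plan.

    Returns a DataFrame with one row per implant: the six metric columns
    plus registration_method, jaw, guide_support and any extra factors.
    """
    if effects is None:
        effects = GroupEffects()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    scenario = generate_scenario(config, rng=rng)
    sites = scenario.planned_implants
    true = scenario.true_transform

    records = []
    i_global = 0
    for (reg, jaw, sup), count in sorted(design.cells.items()):
        use_surface = reg == "dental_surface" and effects.surface_mode_for_dental_surface
        mode = "dental_surface" if use_surface else "fiducial_marker"
        cell_config = config
        if use_surface and effects.surface_sigma_scale != 1.0:
            cell_config = replace(
                config, surface_sigma_mm=config.surface_sigma_mm * effects.surface_sigma_scale
            )
        scale = 1.0
        if jaw == "maxilla":
            scale *= effects.maxilla_guide_scale
        if sup == "distal_extension":
            scale *= effects.distal_extension_guide_scale

        for _ in range(count):
            planned = sites[i_global % len(sites)]
            corr = corrupt_correspondences(scenario, mode, cell_config, rng=rng)
            est = rigid_point_register(corr).transform
            placed = simulate_placement(
                planned, (est, true), config, rng=rng, guide_sigma_scale=scale
            )
            planned_cbct = true.apply_implant(planned)
            factors = {
                "registration_method": reg,
                "jaw": jaw,
                "guide_support": sup,
            }
            for name, levels in design.extra_factors.items():
                factors[name] = levels[rng.integers(0, len(levels))]
            rec = measure_deviations(
                replace(planned_cbct, id=f"imp{i_global + 1}", factors=factors), placed
            )
            records.append(rec)
            i_global += 1
    return cohort_frame(records)
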