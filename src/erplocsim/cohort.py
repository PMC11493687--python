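"""Subject cohorts: per-subject head geometries, a template model, leadfields.

Each synthetic subject is the base geometry with (a) independent lognormal
jitter on the shell radii and (b) a small random rigid rotation of the
electrode cap — the cap as it actually sat on this subject's head. A
subject-specific head model (built from the subject's own anatomy with
digitized electrodes) knows the true cap placement; a template model
assumes the nominal placement. On concentric spheres this per-channel
forward-model mismatch is the dominant, physically meaningful analogue of
anatomical variability: pure radial scaling barely changes leadfield
topography, and rotating a spherically symmetric anatomy under the cap is
unobservable, but a rotated cap shifts every channel's gain pattern
tangentially by ~r*theta. The template model plays the role of an
average-anatomy (fsaverage-like) head model: its radii are the arithmetic
mean of the subject radii and its cap placement the mean rotation
vector. Every subject gets leadfields for the two four-shell FEM
conductivity presets and for a three-shell BEM-style collapse of its own
geometry (CSF shell removed, brain extended outward); the template gets the
same three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import InvalidArgumentError
from .forward import compute_leadfield
from .headmodel import (
    CONDUCTIVITY_PRESETS,
    ElectrodeMontage,
    Leadfield,
    ShellModel,
    SourceSpace,
    make_shell_model,
    make_source_space,
)

#: Leadfield variants computed per head geometry.
MODEL_PRESETS = ("fem_meta", "fem_default", "bem_default")


@dataclass(frozen=True)
class SubjectModel:
    """One head geometry with its montage, dipole grid and leadfields."""

    shell_model: ShellModel  # 4-shell fem geometry (the reference geometry)
    montage: ElectrodeMontage  # shared cap projected onto this outer shell
    sources: SourceSpace
    leadfields: dict[str, Leadfield]  # keyed by preset name
    radius_factors: np.ndarray  # lognormal perturbation applied to base radii
    cap_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    subject_id: str = "subject"


@dataclass(frozen=True)
class SubjectCohort:
    subjects: tuple[SubjectModel, ...]
    template: SubjectModel
    montage: ElectrodeMontage  # the shared, unprojected cap
    seed: int
    base_radii: np.ndarray
    radius_jitter_sd: float
    spacing_mm: float
    eccentricity: float

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _collapse_to_bem(radii_4: np.ndarray) -> ShellModel:
    """Three-shell BEM-analogue of a four-shell geometry: drop the CSF shell
    and let the brain compartment extend to the former CSF outer radius."""
    return make_shell_model("bem_default", radii_4[1:])


def _build_subject(
    radii_4: np.ndarray,
    montage: ElectrodeMontage,
    spacing_mm: float,
    eccentricity: float,
    factors: np.ndarray,
    subject_id: str,
    rotation: np.ndarray | None = None,
) -> SubjectModel:
    fem_meta = make_shell_model("fem_meta", radii_4)
    fem_default = make_shell_model("fem_default", radii_4)
    bem = _collapse_to_bem(radii_4)
    if rotation is not None and not np.array_equal(rotation, np.eye(3)):
        montage = ElectrodeMontage(
            montage.labels,
            montage.positions @ rotation.T,
            montage_id=montage.montage_id,
        )
    sub_montage = montage.projected_to(fem_meta.r_outer)
    sources = make_source_space(fem_meta, spacing_mm, eccentricity)
    leadfields = {
        "fem_meta": compute_leadfield(fem_meta, sub_montage, sources),
        "fem_default": compute_leadfield(fem_default, sub_montage, sources),
        "bem_default": compute_leadfield(bem, sub_montage, sources),
    }
    return SubjectModel(
        shell_model=fem_meta,
        montage=sub_montage,
        sources=sources,
        leadfields=leadfields,
        radius_factors=factors,
        cap_rotation=np.eye(3) if rotation is None else rotation,
        subject_id=subject_id,
    )


def make_cohort(
    n_subjects: int,
    base_radii=None,
    radius_jitter_sd: float = 0.05,
    preset: str = "fem_meta",
    montage: ElectrodeMontage | None = None,
    spacing_mm: float = 3.0,
    seed: int = 0,
    eccentricity: float = 0.85,
    rotation_sd_deg: float = 12.0,
) -> SubjectCohort:
    """Generate a seeded cohort of perturbed head models plus their template.

    Subject radii are ``base_radii * exp(sd * z)`` with independent standard
    normal draws per shell, re-sorted to remain increasing; each subject's
    electrode cap is rotated by a random rotation vector with
    ``rotation_sd_deg`` per-axis SD (the cap placement on that head).
    Template radii are the exact arithmetic mean of the subject radii, the
    template cap placement the exact mean rotation vector.
    """
    if n_subjects < 2:
        raise InvalidArgumentError("a cohort needs at least 2 subjects")
    if not 0.0 <= radius_jitter_sd <= 0.15:
        raise InvalidArgumentError("radius_jitter_sd must lie in [0, 0.15]")
    if preset not in CONDUCTIVITY_PRESETS:
        raise InvalidArgumentError(f"unknown preset {preset!r}")
    if base_radii is None:
        base_radii = (0.083, 0.087, 0.092, 0.100)
    base_radii = np.asarray(base_radii, dtype=float)
    if base_radii.size != 4:
        raise InvalidArgumentError("base_radii must have 4 entries (fem geometry)")
    if montage is None:
        from .headmodel import make_montage

        montage = make_montage(128, float(base_radii[-1]), seed=seed)

    if rotation_sd_deg < 0:
        raise InvalidArgumentError("rotation_sd_deg must be non-negative")
    rng = np.random.default_rng(seed)
    all_factors = np.exp(radius_jitter_sd * rng.standard_normal((n_subjects, 4)))
    subj_radii = np.sort(base_radii[None, :] * all_factors, axis=1)
    rotvecs = np.deg2rad(rotation_sd_deg) * rng.standard_normal((n_subjects, 3))

    subjects = tuple(
        _build_subject(
            subj_radii[i],
            montage,
            spacing_mm,
            eccentricity,
            all_factors[i],
            subject_id=f"sub-{i + 1:02d}",
            rotation=Rotation.from_rotvec(rotvecs[i]).as_matrix(),
        )
        for i in range(n_subjects)
    )
    template_radii = subj_radii.mean(axis=0)
    if np.all(subj_radii == subj_radii[0]):
        template_radii = subj_radii[0]  # exact mean of identical rows
    mean_rotvec = rotvecs.mean(axis=0)
    template = _build_subject(
        template_radii,
        montage,
        spacing_mm,
        eccentricity,
        np.ones(4),
        subject_id="template",
        rotation=Rotation.from_rotvec(mean_rotvec).as_matrix()
        if np.any(mean_rotvec)
        else None,
    )
    return SubjectCohort(
        subjects=subjects,
        template=template,
        montage=montage,
        seed=seed,
        base_radii=base_radii,
        radius_jitter_sd=radius_jitter_sd,
        spacing_mm=spacing_mm,
        eccentricity=eccentricity,
    )


def morph_to_template(
    values: np.ndarray,
    subject_sources: SourceSpace,
    template_sources: SourceSpace,
) -> np.ndarray:
    """Nearest-neighbor morph of a per-dipole field onto the template grid.

    Both grids are normalized to unit radius; each template dipole takes the
    value of the angularly nearest subject dipole. No values are invented.
    """
    values = np.asarray(values, dtype=float)
    if subject_sources.n_dipoles == 0 or template_sources.n_dipoles == 0:
        raise InvalidArgumentError("source spaces must be non-empty")
    if values.shape[0] != subject_sources.n_dipoles:
        raise InvalidArgumentError("values must have one entry per subject dipole")
    sub_u = subject_sources.radial_units
    tmp_u = template_sources.radial_units
    _, idx = cKDTree(sub_u).query(tmp_u, k=1)
    return values[idx]
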