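"""Synthetic head geometry: electrode montages, layered-sphere models, dipole grids.

The study's head models are concentric conducting spheres. A "detailed"
model has four shells (brain, CSF, skull, scalp) and emulates an FEM head
model that resolves cerebrospinal fluid; a "simple" model has three shells
(brain, skull, scalp) and emulates a BEM model, which cannot represent CSF.
Electrodes live on the outermost shell; dipoles on a spherical surface
inside the brain shell. All coordinates are head-centered Cartesian meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, ResourceLimitError

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Conductivity presets, innermost shell first, in S/m.
#: fem_meta     - meta-analysis values: gray matter, CSF, compact bone, scalp.
#: fem_default  - Brainstorm-style defaults: gray matter, CSF, compact bone, scalp.
#: bem_default  - classic three-layer values: brain, skull, scalp.
CONDUCTIVITY_PRESETS: dict[str, tuple[float, ...]] = {
    "fem_meta": (0.47, 1.71, 0.006, 0.41),
    "fem_default": (0.33, 1.79, 0.008, 0.43),
    "bem_default": (0.33, 0.006, 0.33),
}

#: Conventional shell radii in meters (brain[, CSF], skull, scalp).
DEFAULT_RADII_4 = (0.083, 0.087, 0.092, 0.100)
DEFAULT_RADII_3 = (0.087, 0.092, 0.100)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named EEG sensors on the outer shell surface."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_sensors, 3), meters
    montage_id: str = "montage"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidArgumentError("positions must be (n, 3)")
        if len(self.labels) != pos.shape[0]:
            raise InvalidArgumentError("labels and positions disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("sensor labels must be unique")
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def projected_to(self, outer_radius: float) -> "ElectrodeMontage":
        """Radially project every sensor onto a sphere of the given radius."""
        norms = np.linalg.norm(self.positions, axis=1, keepdims=True)
        return ElectrodeMontage(
            self.labels, self.positions / norms * outer_radius, self.montage_id
        )


@dataclass(frozen=True)
class ShellModel:
    """Concentric-shell head geometry with per-shell conductivities."""

    radii: np.ndarray  # meters, strictly increasing, innermost -> outermost
    conductivities: np.ndarray  # S/m, one per shell
    name: str = "custom"

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        cond = np.asarray(self.conductivities, dtype=float)
        if radii.ndim != 1 or cond.shape != radii.shape:
            raise InvalidArgumentError("radii and conductivities must match in length")
        if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
            raise InvalidArgumentError("radii must be positive and strictly increasing")
        if np.any(cond <= 0):
            raise InvalidArgumentError("conductivities must be positive")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductivities", cond)

    @property
    def n_shells(self) -> int:
        return self.radii.size

    @property
    def r_brain(self) -> float:
        return float(self.radii[0])

    @property
    def r_outer(self) -> float:
        return float(self.radii[-1])


@dataclass(frozen=True)
class SourceSpace:
    """Dipole grid on a spherical surface inside the brain shell."""

    positions: np.ndarray  # (n_dipoles, 3), meters
    nominal_spacing_mm: float
    per_dipole_volume_mm3: float
    source_space_id: str = "sources"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
            raise InvalidArgumentError("positions must be a non-empty (n, 3) array")
        object.__setattr__(self, "positions", pos)

    @property
    def n_dipoles(self) -> int:
        return self.positions.shape[0]

    @property
    def radial_units(self) -> np.ndarray:
        """Unit outward vector at each dipole (radial orientation)."""
        return self.positions / np.linalg.norm(self.positions, axis=1, keepdims=True)


@dataclass(frozen=True)
class Leadfield:
    """Average-referenced gain matrix, sensors x (3 * sources).

    Columns come in contiguous triples per source, one per canonical
    moment direction (x, y, z), in volts per A*m.
    """

    gain: np.ndarray
    reference: str = "average"
    source_space_id: str = ""
    montage_id: str = ""
    shell_model_id: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if g.ndim != 2 or g.shape[1] % 3 != 0:
            raise InvalidArgumentError("gain must be (n_sensors, 3*n_sources)")
        if not np.all(np.isfinite(g)):
            raise InvalidArgumentError("gain must be finite")
        object.__setattr__(self, "gain", g)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3


def make_shell_model(preset: str, radii) -> ShellModel:
    """Build a ShellModel from a named conductivity preset.

    ``fem_meta`` and ``fem_default`` require four radii (brain, CSF, skull,
    scalp); ``bem_default`` requires three (brain, skull, scalp).
    """
    if preset not in CONDUCTIVITY_PRESETS:
        raise InvalidArgumentError(
            f"unknown preset {preset!r}; choose from {sorted(CONDUCTIVITY_PRESETS)}"
        )
    cond = CONDUCTIVITY_PRESETS[preset]
    radii = np.asarray(radii, dtype=float)
    if radii.size != len(cond):
        raise InvalidArgumentError(
            f"preset {preset!r} needs {len(cond)} radii, got {radii.size}"
        )
    return ShellModel(radii=radii, conductivities=np.array(cond), name=preset)


def make_montage(n_sensors: int, outer_radius: float, seed: int = 0) -> ElectrodeMontage:
    """Quasi-uniform electrode cap on the upper sphere.

    Sensors are placed on a Fibonacci lattice restricted to polar angles
    0-120 degrees (no face/neck coverage), approximating a high-density EEG
    cap. The seed only rotates the lattice in azimuth.
    """
    if n_sensors < 8:
        raise InvalidArgumentError("a montage needs at least 8 sensors")
    if outer_radius <= 0:
        raise InvalidArgumentError("outer_radius must be positive")
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_sensors)
    z_lo = np.cos(2.0 * np.pi / 3.0)  # cos(120 deg) = -0.5
    z = 1.0 - (i + 0.5) / n_sensors * (1.0 - z_lo)
    phi = phi0 + i * GOLDEN_ANGLE
    s = np.sqrt(1.0 - z**2)
    pos = outer_radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    labels = tuple(f"E{k + 1:03d}" for k in range(n_sensors))
    return ElectrodeMontage(labels, pos, montage_id=f"cap{n_sensors}-s{seed}")


def make_source_space(
    model: ShellModel,
    spacing_mm: float = 3.0,
    eccentricity: float = 0.85,
    max_dipoles: int = 50_000,
) -> SourceSpace:
    """Fibonacci grid of dipoles on the sphere at ``eccentricity * r_brain``.

    The dipole count is chosen so that the sphere area per dipole is
    ``spacing_mm**2``, which makes nearest-neighbor distances track the
    nominal spacing. ``per_dipole_volume`` is ``spacing_mm**3`` so that the
    volume-based dispersion metric reduces to a count ratio.
    """
    if spacing_mm <= 0:
        raise InvalidArgumentError("spacing must be positive")
    if not 0.0 < eccentricity < 1.0:
        raise InvalidArgumentError("eccentricity must lie in (0, 1)")
    r_src = eccentricity * model.r_brain
    if r_src >= model.r_brain - 1e-3:
        raise InvalidArgumentError(
            "source sphere must stay >= 1 mm inside the brain shell"
        )
    r_mm = r_src * 1e3
    n = int(round(4.0 * np.pi * r_mm**2 / spacing_mm**2))
    n = max(n, 12)
    if n > max_dipoles:
        raise ResourceLimitError(
            f"requested grid has {n} dipoles, exceeding the cap of {max_dipoles}"
        )
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * GOLDEN_ANGLE
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = r_src * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return SourceSpace(
        positions=pos,
        nominal_spacing_mm=spacing_mm,
        per_dipole_volume_mm3=spacing_mm**3,
        source_space_id=f"{model.name}-sph{spacing_mm:g}mm-e{eccentricity:g}",
    )
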