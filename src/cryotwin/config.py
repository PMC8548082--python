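"""Declarative experiment description: microscope, detector, scan and sample.

The whole simulation is driven by a single YAML document with top-level
keys ``beam``, ``lens``, ``detector``, ``scan``, ``sample`` and
``simulation``.  Every field has a documented default chosen to be
consistent with a 300 keV high-end cryo-microscope, so an empty document
is a valid configuration.  Validation is strict: unknown keys and
violated physical invariants are rejected with the offending key path.

Angles are degrees in configuration files and radians internally; the
conversion happens at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "BeamModel",
    "DriftModel",
    "LensModel",
    "DetectorModel",
    "ScanModel",
    "NoIce",
    "RandomWaterIce",
    "GRFIce",
    "PlaneGeometrySpec",
    "CylinderGeometrySpec",
    "ParticleRequest",
    "SampleSpec",
    "SimulationOptions",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "default_config_yaml",
    "ScanEntry",
    "generate_scan",
]


class ConfigError(ValueError):
    """Raised when a configuration document is invalid; names the bad key."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DriftModel(_StrictModel):
    """Beam drift as a function of acquisition index.

    ``random`` draws an independent Gaussian offset per image with the given
    RMS amplitude; ``sinusoidal`` follows ``amplitude * sin(2*pi*k/period)``.
    The drift offset is applied to the specimen position before the exposure
    (i.e. the recorded image is of the already-drifted specimen).
    """

    kind: Literal["none", "random", "sinusoidal"] = "none"
    amplitude: float = Field(default=0.0, ge=0.0, description="A")
    period: float = Field(default=10.0, gt=0.0, description="images per cycle")
    seed: int = 0


class BeamModel(_StrictModel):
    """Electron beam: energy, spreads, flux and drift."""

    energy: float = Field(default=300.0, gt=0.0, description="keV")
    energy_spread: float = Field(default=0.8, ge=0.0, description="dE, eV")
    voltage_spread: float = Field(default=0.8, ge=0.0, description="dV/V, ppm")
    current_spread: float = Field(default=0.33, ge=0.0, description="dI/I, ppm")
    source_spread: float = Field(default=0.1, ge=0.0, description="theta_c, mrad")
    flux: float = Field(default=10.0, gt=0.0, description="e-/A^2/s")
    drift: DriftModel = Field(default_factory=DriftModel)


class LensModel(_StrictModel):
    """Objective lens aberrations; underfocus is positive defocus."""

    defocus: float = Field(default=25000.0, description="A (2.5 um underfocus)")
    spherical_aberration: float = Field(default=2.7, ge=0.0, description="Cs, mm")
    chromatic_aberration: float = Field(default=2.7, ge=0.0, description="Cc, mm")
    phase_plate_shift: float = Field(default=0.0, description="rad")


class DetectorModel(_StrictModel):
    """Pixelated detector with a parametric DQE curve.

    ``DQE(q) = dqe0 * (1 - dqe_falloff * (q / q_nyquist)^2)`` clipped at 0.
    """

    nx: int = Field(default=256, ge=1)
    ny: int = Field(default=256, ge=1)
    pixel_size: float = Field(default=1.0, gt=0.0, description="A")
    dqe0: float = Field(default=0.8, gt=0.0, le=1.0)
    dqe_falloff: float = Field(default=0.5, ge=0.0)


class ScanModel(_StrictModel):
    """Single-axis tilt scheme.

    ``fixed_count`` spaces ``num_images`` angles uniformly over
    [-max_tilt, +max_tilt] including both endpoints; ``fixed_increment``
    steps by ``increment`` degrees through zero.  ``dose_symmetric``
    ordering acquires in increasing |angle| with the positive branch first
    on ties.
    """

    axis: Tuple[float, float, float] = (0.0, 1.0, 0.0)
    max_tilt: float = Field(default=60.0, gt=0.0, le=90.0, description="deg")
    mode: Literal["fixed_count", "fixed_increment"] = "fixed_count"
    num_images: int = Field(default=61, ge=1)
    increment: float = Field(default=2.0, gt=0.0, description="deg")
    exposure: float = Field(default=1.0, gt=0.0, description="s per image")
    translation: Tuple[float, float] = Field(
        default=(0.0, 0.0), description="A per image, applied pre-exposure"
    )
    ordering: Literal["dose_symmetric", "sequential"] = "dose_symmetric"

    @model_validator(mode="after")
    def _check_axis(self) -> "ScanModel":
        n = float(np.linalg.norm(self.axis))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"scan.axis must be a unit vector (|axis| = {n:.4g})")
        return self


class GRFIce(_StrictModel):
    """Continuum amorphous-ice model: Gaussian random field parameters."""

    kind: Literal["grf"] = "grf"
    mean: float = Field(default=4.87, description="mean inner potential, V")
    variance: float = Field(default=30.0, ge=0.0, description="V^2")
    correlation_length: float = Field(default=0.8, gt=0.0, description="A")
    seed: int = 0


class RandomWaterIce(_StrictModel):
    """Atomistic ice: rigid water molecules at random positions/orientations."""

    kind: Literal["random_water"] = "random_water"
    density: float = Field(default=0.031, gt=0.0, description="molecules/A^3")
    seed: int = 0


class NoIce(_StrictModel):
    kind: Literal["none"] = "none"


class PlaneGeometrySpec(_StrictModel):
    shape: Literal["plane"] = "plane"
    x_width: float = Field(default=600.0, gt=0.0, description="A")
    y_width: float = Field(default=256.0, gt=0.0, description="A")
    z_depth: float = Field(default=300.0, gt=0.0, description="A")


class CylinderGeometrySpec(_StrictModel):
    shape: Literal["cylinder"] = "cylinder"
    length: float = Field(default=256.0, gt=0.0, description="A, along axis")
    radius: float = Field(default=150.0, gt=0.0, description="A")


class ParticleRequest(_StrictModel):
    model_id: str = "phantom"
    count: int = Field(default=1, ge=0)
    positions: Optional[List[Tuple[float, float, float]]] = None
    orientations: Optional[List[Tuple[float, float, float, float]]] = None
    random_orientations: bool = False


class SampleSpec(_StrictModel):
    """Sample geometry, particle content and ice model."""

    geometry: PlaneGeometrySpec | CylinderGeometrySpec = Field(
        default_factory=PlaneGeometrySpec, discriminator="shape"
    )
    particles: List[ParticleRequest] = Field(default_factory=list)
    ice: NoIce | RandomWaterIce | GRFIce = Field(
        default_factory=GRFIce, discriminator="kind"
    )
    seed: int = 0


class SimulationOptions(_StrictModel):
    """Numerical controls of the multislice image simulation."""

    slice_thickness: float = Field(default=5.0, gt=0.0, description="t_s, A")
    pixel_size: float = Field(default=1.0, gt=0.0, description="potential px, A")
    damage_sensitivity: float = Field(
        default=0.022, ge=0.0, description="S_E, A^2/e-"
    )
    seed: int = 0


class SimulationConfig(_StrictModel):
    beam: BeamModel = Field(default_factory=BeamModel)
    lens: LensModel = Field(default_factory=LensModel)
    detector: DetectorModel = Field(default_factory=DetectorModel)
    scan: ScanModel = Field(default_factory=ScanModel)
    sample: SampleSpec = Field(default_factory=SampleSpec)
    simulation: SimulationOptions = Field(default_factory=SimulationOptions)


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_config(yaml_text: str) -> SimulationConfig:
    """Parse and validate a YAML configuration document.

    An empty document yields the documented defaults.  Unknown keys and
    invariant violations raise :class:`ConfigError` naming the key path.
    """
    data = yaml.safe_load(yaml_text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level YAML document must be a mapping")
    try:
        return SimulationConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def dump_config(config: SimulationConfig) -> str:
    """Serialize a configuration back to YAML (round-trips with load_config)."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)


def default_config_yaml() -> str:
    """A commented default configuration document."""
    body = dump_config(SimulationConfig())
    header = (
        "# cryotwin simulation configuration\n"
        "# Units: lengths A, energy keV, defocus A (underfocus positive),\n"
        "# Cs/Cc mm, flux e-/A^2/s, angles deg, exposure s.\n"
    )
    return header + body


# ---------------------------------------------------------------------------
# Scan plan expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanEntry:
    """One planned exposure of the tilt series."""

    angle: float  # deg
    index: int  # acquisition order, 0-based
    cumulative_exposure: float  # s, including this exposure


def _scan_angles(scan: ScanModel) -> np.ndarray:
    if scan.mode == "fixed_count":
        if scan.num_images < 1:
            raise ValueError("scan.num_images must be >= 1")
        if scan.num_images == 1:
            return np.array([0.0])
        return np.linspace(-scan.max_tilt, scan.max_tilt, scan.num_images)
    # fixed increment, symmetric through zero
    n_half = int(np.floor(scan.max_tilt / scan.increment + 1e-9))
    pos = np.arange(1, n_half + 1) * scan.increment
    return np.concatenate([-pos[::-1], [0.0], pos])


def generate_scan(scan: ScanModel) -> List[ScanEntry]:
    """Expand a scan model into an ordered acquisition plan.

    The returned entries carry the acquisition index and the cumulative
    exposure time (seconds, inclusive of the entry's own exposure), which
    together with the beam flux define the accumulated dose seen by the
    beam-damage model.  Dose-symmetric ordering is non-decreasing in
    |angle|, positive branch first on ties.
    """
    angles = _scan_angles(scan)
    if scan.ordering == "dose_symmetric":
        # sort by |angle|; ties broken positive-first (documented convention)
        order = np.lexsort((-np.sign(angles), np.abs(angles)))
        angles = angles[order]
    else:
        angles = np.sort(angles)
    return [
        ScanEntry(angle=float(a), index=i, cumulative_exposure=(i + 1) * scan.exposure)
        for i, a in enumerate(angles)
    ]
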