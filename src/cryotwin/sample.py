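"""Virtual specimen construction.

Builds the ground-truth sample that the tilt-series simulator images and
the reconstruction loop is scored against: a container geometry (planar
slab or spline-profiled cylinder), particle instances placed without
overlap, an amorphous-ice model, and lossless HDF5 persistence.

Coordinate convention (used by every module downstream): right-handed,
Angstrom units, beam along -z at zero tilt, tilt rotation about +y,
geometry centred at the origin, particle positions are centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
from scipy.interpolate import CubicSpline

from .config import GRFIce, NoIce, RandomWaterIce
from .scattering import ELEMENT_Z

__all__ = [
    "AtomicModel",
    "PlaneGeometry",
    "CylinderGeometry",
    "SampleGeometry",
    "ParticleInstance",
    "Sample",
    "PlacementError",
    "read_atomic_model",
    "make_phantom_particle",
    "place_particles",
    "mill",
    "ice_random_water",
    "ice_grf",
    "sample_store",
    "sample_load",
    "rotation_matrix",
    "random_quaternion",
]

SCHEMA_VERSION = 1
MAX_PLACEMENT_ATTEMPTS = 10_000

IceModel = Union[NoIce, RandomWaterIce, GRFIce]


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------


def rotation_matrix(quaternion: Sequence[float]) -> np.ndarray:
    """Rotation matrix from a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(quaternion, dtype=float)
    n = math.sqrt(w * w + x * x + y * y + z * z)
    if not math.isclose(n, 1.0, rel_tol=1e-6):
        raise ValueError(f"quaternion must be normalized (|q| = {n:.6g})")
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation over SO(3) (Shoemake's subgroup method)."""
    u1, u2, u3 = rng.random(3)
    a, b = math.sqrt(1.0 - u1), math.sqrt(u1)
    return np.array(
        [
            b * math.cos(2 * math.pi * u3),
            a * math.sin(2 * math.pi * u2),
            a * math.cos(2 * math.pi * u2),
            b * math.sin(2 * math.pi * u3),
        ]
    )


# ---------------------------------------------------------------------------
# Atomic model
# ---------------------------------------------------------------------------


@dataclass
class AtomicModel:
    """A set of atoms: element symbols, coordinates (A) and occupancies.

    Atoms with partial occupancy are kept as single records; the occupancy
    weights the atom's potential linearly in the simulator (alternate
    conformers therefore contribute their occupancy-weighted average).
    """

    elements: np.ndarray  # (n,) unicode symbols
    coords: np.ndarray  # (n, 3) float, A
    occupancy: np.ndarray  # (n,) float

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.occupancy = np.asarray(self.occupancy, dtype=float).reshape(-1)
        if not (len(self.elements) == len(self.coords) == len(self.occupancy)):
            raise ValueError("elements/coords/occupancy length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        unknown = {e.upper() for e in self.elements} - set(ELEMENT_Z)
        if unknown:
            raise ValueError(f"unknown element symbols: {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0) if self.n_atoms else np.zeros(3)

    def bounding_radius(self) -> float:
        if self.n_atoms == 0:
            return 0.0
        return float(np.linalg.norm(self.coords - self.centroid(), axis=1).max())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        coords = self.coords @ rotation.T + np.asarray(translation, float)
        return AtomicModel(self.elements.copy(), coords, self.occupancy.copy())

    @staticmethod
    def concatenate(models: Sequence["AtomicModel"]) -> "AtomicModel":
        models = [m for m in models if m.n_atoms]
        if not models:
            return AtomicModel(np.empty(0, "U2"), np.empty((0, 3)), np.empty(0))
        return AtomicModel(
            np.concatenate([m.elements for m in models]),
            np.concatenate([m.coords for m in models]),
            np.concatenate([m.occupancy for m in models]),
        )


def read_atomic_model(path: str) -> AtomicModel:
    """Read a PDB or mmCIF coordinate file into an :class:`AtomicModel`.

    Every ATOM/HETATM record of the first model becomes one atom (all
    altloc records are kept, carrying their occupancies).  Element symbols
    not in the scattering table raise with the symbol named.
    """
    import gemmi

    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with context
        raise ValueError(f"could not parse coordinate file {path!r}: {exc}") from exc
    elements: List[str] = []
    coords: List[Tuple[float, float, float]] = []
    occ: List[float] = []
    if len(structure) == 0:
        raise ValueError(f"{path!r} contains no models")
    model = structure[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                elements.append(atom.element.name.upper())
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                occ.append(atom.occ)
    return AtomicModel(np.array(elements), np.array(coords), np.array(occ))


def make_phantom_particle(
    seed: int,
    n_atoms: int,
    radius: float,
    *,
    mean_density: Optional[float] = None,
) -> AtomicModel:
    """Deterministic phantom macromolecule: random atoms in a ball.

    Atoms are uniformly distributed in a ball of the given radius with a
    protein-like C/N/O/S element mix; a uniform random cloud has no
    accidental point symmetry, so orientation recovery is testable.  When
    ``mean_density`` (atoms/A^3) is given, occupancies are scaled so the
    phantom carries the integrated potential of a particle of that atom
    density — the coarse-graining used by the desk-scale sweeps.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_atoms, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.random(n_atoms) ** (1.0 / 3.0)
    coords = directions * radii[:, None]
    # protein-like heavy-atom composition
    symbols = rng.choice(
        np.array(["C", "N", "O", "S"]), size=n_atoms, p=[0.62, 0.17, 0.20, 0.01]
    )
    occupancy = np.ones(n_atoms)
    if mean_density is not None:
        volume = 4.0 / 3.0 * math.pi * radius**3
        occupancy *= mean_density * volume / n_atoms
    return AtomicModel(symbols, coords, occupancy)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class PlaneGeometry:
    """Planar slab centred at the origin: |x| <= x_width/2 etc."""

    x_width: float
    y_width: float
    z_depth: float

    def __post_init__(self) -> None:
        if min(self.x_width, self.y_width, self.z_depth) <= 0:
            raise ValueError("plane dimensions must be > 0")

    @property
    def shape(self) -> str:
        return "plane"

    def volume(self) -> float:
        return self.x_width * self.y_width * self.z_depth

    def bounding_box(self) -> np.ndarray:
        h = 0.5 * np.array([self.x_width, self.y_width, self.z_depth])
        return np.stack([-h, h])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(points)
        h = 0.5 * np.array([self.x_width, self.y_width, self.z_depth]) - margin
        return np.all(np.abs(p) <= h, axis=-1)


@dataclass
class CylinderGeometry:
    """Cylinder along +y, centred at the origin, with a spline profile.

    ``profile`` is a list of (position-along-axis, radius, (x, z) centre
    offset) knots; radius and offsets are interpolated with cubic splines,
    which lets the cylinder take 'natural' non-ideal shapes.  A single knot
    (or equal-radius knots) is an exact right circular cylinder.
    """

    length: float
    radius: float
    profile: Optional[List[Tuple[float, float, Tuple[float, float]]]] = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("cylinder dimensions must be > 0")
        self._splines = None
        if self.profile is not None:
            pos = np.array([k[0] for k in self.profile], float)
            if len(pos) >= 2 and not np.all(np.diff(pos) > 0):
                raise ValueError("profile positions must be strictly increasing")
            rad = np.array([k[1] for k in self.profile], float)
            off = np.array([k[2] for k in self.profile], float).reshape(-1, 2)
            if np.any(rad <= 0):
                raise ValueError("profile radii must be > 0")
            if len(pos) == 1:
                self._splines = (lambda s: np.full_like(s, rad[0], dtype=float),
                                 lambda s: np.tile(off[0], (len(np.atleast_1d(s)), 1)))
            else:
                rs = CubicSpline(pos, rad)
                os_ = CubicSpline(pos, off)
                self._splines = (rs, os_)

    @property
    def shape(self) -> str:
        return "cylinder"

    def radius_at(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_1d(np.asarray(y, float))
        if self._splines is None:
            return np.full(y.shape, self.radius)
        return np.asarray(self._splines[0](y), float)

    def offset_at(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_1d(np.asarray(y, float))
        if self._splines is None:
            return np.zeros(y.shape + (2,))
        return np.asarray(self._splines[1](y), float).reshape(y.shape + (2,))

    def volume(self) -> float:
        ys = np.linspace(-self.length / 2, self.length / 2, 513)
        r = self.radius_at(ys)
        return float(np.trapezoid(math.pi * r**2, ys))

    def bounding_box(self) -> np.ndarray:
        ys = np.linspace(-self.length / 2, self.length / 2, 257)
        r = self.radius_at(ys)
        off = self.offset_at(ys)
        rx = float((np.abs(off[:, 0]) + r).max())
        rz = float((np.abs(off[:, 1]) + r).max())
        return np.array([[-rx, -self.length / 2, -rz], [rx, self.length / 2, rz]])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(points)
        inside_y = np.abs(p[:, 1]) <= self.length / 2 - margin
        r = self.radius_at(p[:, 1])
        off = self.offset_at(p[:, 1])
        dr = np.hypot(p[:, 0] - off[:, 0], p[:, 2] - off[:, 1])
        return inside_y & (dr <= r - margin)


SampleGeometry = Union[PlaneGeometry, CylinderGeometry]


# ---------------------------------------------------------------------------
# Sample container
# ---------------------------------------------------------------------------


@dataclass
class ParticleInstance:
    model_id: str
    position: np.ndarray  # centroid, A
    orientation: np.ndarray  # unit quaternion (w, x, y, z)
    bounding_radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        self.orientation = np.asarray(self.orientation, float).reshape(4)
        n = np.linalg.norm(self.orientation)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            raise ValueError(f"orientation quaternion not normalized (|q|={n:.4g})")


@dataclass
class Sample:
    """Ground-truth specimen: geometry, placed particles, atoms and ice."""

    geometry: SampleGeometry
    particles: List[ParticleInstance] = field(default_factory=list)
    models: Dict[str, AtomicModel] = field(default_factory=dict)
    ice: IceModel = field(default_factory=NoIce)
    ice_atoms: Optional[AtomicModel] = None
    milled_region: Optional[str] = None

    def particle_atoms(self, instance: ParticleInstance) -> AtomicModel:
        """World-frame atoms of one particle instance."""
        model = self.models[instance.model_id]
        rot = rotation_matrix(instance.orientation)
        return model.transformed(rot, instance.position - rot @ model.centroid())

    def all_atoms(self) -> AtomicModel:
        parts = [self.particle_atoms(p) for p in self.particles]
        if self.ice_atoms is not None:
            parts.append(self.ice_atoms)
        return AtomicModel.concatenate(parts)


class PlacementError(RuntimeError):
    """Raised when the requested particle count cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} particles within "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts each"
        )
        self.requested = requested
        self.achieved = achieved


def place_particles(
    geometry: SampleGeometry,
    models: Dict[str, AtomicModel],
    requests: Sequence[dict],
    seed: int = 0,
    ice: Optional[IceModel] = None,
) -> Sample:
    """Place particle instances into a geometry without overlaps.

    Each request is a mapping with ``model_id`` plus either ``count``
    (random placement) or explicit ``positions`` (and optional
    ``orientations``); ``random_orientations`` draws uniform SO(3)
    rotations, otherwise the identity pose is used.  A single requested
    particle with no explicit position defaults to the geometry centre.
    Random placement is rejection sampling, bounded at
    ``MAX_PLACEMENT_ATTEMPTS`` per particle; overlap is tested on bounding
    spheres and containment requires the full bounding sphere inside the
    geometry.
    """
    rng = np.random.default_rng(seed)
    placed: List[ParticleInstance] = []
    identity_q = np.array([1.0, 0.0, 0.0, 0.0])
    box = geometry.bounding_box()
    total_requested = sum(int(r.get("count", len(r.get("positions") or []) or 1))
                          for r in requests)

    def overlaps(pos: np.ndarray, radius: float) -> bool:
        return any(
            np.linalg.norm(pos - p.position) < radius + p.bounding_radius
            for p in placed
        )

    for req in requests:
        model_id = req["model_id"]
        radius = models[model_id].bounding_radius()
        positions = req.get("positions")
        if positions is not None:
            orientations = req.get("orientations")
            for i, pos in enumerate(positions):
                pos = np.asarray(pos, float)
                q = (np.asarray(orientations[i], float)
                     if orientations is not None else identity_q)
                if not geometry.contains(pos[None], margin=radius)[0]:
                    raise ValueError(
                        f"explicit position {pos.tolist()} (+margin {radius:.1f} A) "
                        f"is outside the geometry"
                    )
                if overlaps(pos, radius):
                    raise ValueError(f"explicit position {pos.tolist()} overlaps")
                placed.append(ParticleInstance(model_id, pos, q, radius))
            continue
        count = int(req.get("count", 1))
        random_orient = bool(req.get("random_orientations", False))
        if count == 1 and total_requested == 1 and not random_orient:
            # lone particle defaults to the geometry centre
            centre = np.zeros(3)
            if not geometry.contains(centre[None], margin=radius)[0]:
                raise PlacementError(1, 0)
            placed.append(ParticleInstance(model_id, centre, identity_q, radius))
            continue
        for _ in range(count):
            for attempt in range(MAX_PLACEMENT_ATTEMPTS):
                pos = box[0] + rng.random(3) * (box[1] - box[0])
                if not geometry.contains(pos[None], margin=radius)[0]:
                    continue
                if overlaps(pos, radius):
                    continue
                q = random_quaternion(rng) if random_orient else identity_q
                placed.append(ParticleInstance(model_id, pos, q, radius))
                break
            else:
                raise PlacementError(total_requested, len(placed))

    return Sample(
        geometry=geometry,
        particles=placed,
        models={r["model_id"]: models[r["model_id"]] for r in requests},
        ice=ice if ice is not None else NoIce(),
    )


def mill(sample: Sample, region: Callable[[np.ndarray], np.ndarray],
         description: str = "custom") -> Sample:
    """Remove all atoms outside ``region`` (a vectorized point predicate).

    Particle instances are baked to world-frame atom sets so arbitrary
    shapes can be cut; instances left with zero atoms are dropped, and the
    milled region is recorded on the returned sample.
    """
    new_particles: List[ParticleInstance] = []
    new_models: Dict[str, AtomicModel] = {}
    for i, inst in enumerate(sample.particles):
        atoms = sample.particle_atoms(inst)
        keep = np.asarray(region(atoms.coords), bool)
        if not keep.any():
            continue
        baked = AtomicModel(atoms.elements[keep], atoms.coords[keep],
                            atoms.occupancy[keep])
        baked_id = f"{inst.model_id}#milled{i}"
        new_models[baked_id] = baked
        new_particles.append(
            ParticleInstance(baked_id, baked.centroid(),
                             np.array([1.0, 0.0, 0.0, 0.0]),
                             baked.bounding_radius())
        )
    ice_atoms = sample.ice_atoms
    if ice_atoms is not None and ice_atoms.n_atoms:
        keep = np.asarray(region(ice_atoms.coords), bool)
        ice_atoms = AtomicModel(ice_atoms.elements[keep], ice_atoms.coords[keep],
                                ice_atoms.occupancy[keep])
    return Sample(
        geometry=sample.geometry,
        particles=new_particles,
        models=new_models,
        ice=sample.ice,
        ice_atoms=ice_atoms,
        milled_region=description,
    )


# ---------------------------------------------------------------------------
# Ice models
# ---------------------------------------------------------------------------

# rigid water geometry: O at origin, O-H 0.9572 A, H-O-H 104.52 deg
_WATER_LOCAL = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [0.9572 * math.cos(math.radians(104.52)),
         0.9572 * math.sin(math.radians(104.52)), 0.0],
    ]
)
_WATER_ELEMENTS = np.array(["O", "H", "H"])


def ice_random_water(geometry: SampleGeometry, density: float = 0.031,
                     seed: int = 0) -> AtomicModel:
    """Atomistic amorphous ice: randomly placed, randomly oriented waters.

    The molecule count is ``round(density * volume)`` (default density
    0.031 molecules/A^3, ~0.93 g/cm^3 vitreous ice).  No minimum-distance
    constraint is enforced, so molecules may sit at unphysical separations;
    relaxing them would require molecular dynamics and is out of scope.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    count = int(round(density * geometry.volume()))
    if count == 0:
        return AtomicModel(np.empty(0, "U2"), np.empty((0, 3)), np.empty(0))
    rng = np.random.default_rng(seed)
    box = geometry.bounding_box()
    centres = np.empty((count, 3))
    n_placed = 0
    while n_placed < count:
        batch = max(count - n_placed, 256)
        pts = box[0] + rng.random((batch, 3)) * (box[1] - box[0])
        pts = pts[geometry.contains(pts)]
        take = min(len(pts), count - n_placed)
        centres[n_placed:n_placed + take] = pts[:take]
        n_placed += take
    coords = np.empty((count * 3, 3))
    for i in range(count):
        rot = rotation_matrix(random_quaternion(rng))
        coords[3 * i:3 * i + 3] = _WATER_LOCAL @ rot.T + centres[i]
    elements = np.tile(_WATER_ELEMENTS, count)
    return AtomicModel(elements, coords, np.ones(count * 3))


def ice_grf(
    shape: Tuple[int, ...],
    voxel_size: float,
    mean: float,
    variance: float,
    correlation_length: float,
    seed: int = 0,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Gaussian-random-field continuum ice potential on a grid (V).

    The field is Fourier-filtered white noise with a Gaussian-correlation
    power spectrum ``S(k) ~ exp(-k^2 l^2 / 2)`` (correlation function
    ``exp(-r^2 / 2 l^2)``), normalized so the expected sample variance
    equals ``variance`` on the discrete grid, then shifted to ``mean``.
    With a ``mask`` the field is confined to the sample interior and zero
    outside.  The spectrum family is a documented stand-in for a measured
    amorphous-ice structure factor and is pluggable at this boundary.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    rng = np.random.default_rng(seed)
    if variance == 0:
        out = np.full(shape, mean, float)
    else:
        noise = rng.standard_normal(shape)
        spectrum = np.fft.fftn(noise)
        k2 = np.zeros(shape)
        for axis, n in enumerate(shape):
            k = 2.0 * math.pi * np.fft.fftfreq(n, d=voxel_size)
            k2 = k2 + k.reshape([-1 if a == axis else 1 for a in range(len(shape))]) ** 2
        filt = np.exp(-k2 * correlation_length**2 / 4.0)
        field = np.fft.ifftn(spectrum * filt).real
        # expected variance of the filtered field is mean(filt^2); rescale
        field *= math.sqrt(variance / float(np.mean(filt**2)))
        out = mean + field
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------


def _write_geometry(grp: h5py.Group, geometry: SampleGeometry) -> None:
    grp.attrs["shape"] = geometry.shape
    if isinstance(geometry, PlaneGeometry):
        grp.attrs["x_width"] = geometry.x_width
        grp.attrs["y_width"] = geometry.y_width
        grp.attrs["z_depth"] = geometry.z_depth
    else:
        grp.attrs["length"] = geometry.length
        grp.attrs["radius"] = geometry.radius
        if geometry.profile is not None:
            knots = np.array(
                [[p, r, o[0], o[1]] for p, r, o in geometry.profile], float
            )
            grp.create_dataset("profile", data=knots)


def _read_geometry(grp: h5py.Group) -> SampleGeometry:
    shape = grp.attrs["shape"]
    if shape == "plane":
        return PlaneGeometry(float(grp.attrs["x_width"]),
                             float(grp.attrs["y_width"]),
                             float(grp.attrs["z_depth"]))
    profile = None
    if "profile" in grp:
        knots = grp["profile"][()]
        profile = [(float(k[0]), float(k[1]), (float(k[2]), float(k[3])))
                   for k in knots]
    return CylinderGeometry(float(grp.attrs["length"]),
                            float(grp.attrs["radius"]), profile)


def _write_atoms(grp: h5py.Group, model: AtomicModel) -> None:
    grp.create_dataset("elements", data=model.elements.astype("S2"))
    grp.create_dataset("coords", data=model.coords)
    grp.create_dataset("occupancy", data=model.occupancy)


def _read_atoms(grp: h5py.Group) -> AtomicModel:
    return AtomicModel(
        grp["elements"][()].astype("U2"),
        grp["coords"][()],
        grp["occupancy"][()],
    )


def sample_store(sample: Sample, path: str) -> None:
    """Persist a sample to a self-describing HDF5 file (schema version 1)."""
    with h5py.File(path, "w") as f:
        f.attrs["application"] = "cryotwin"
        f.attrs["schema_version"] = SCHEMA_VERSION
        _write_geometry(f.create_group("geometry"), sample.geometry)
        models = f.create_group("models")
        for mid, model in sample.models.items():
            _write_atoms(models.create_group(mid), model)
        parts = f.create_group("particles")
        parts.create_dataset(
            "model_id",
            data=np.array([p.model_id for p in sample.particles], dtype="S64"),
        )
        parts.create_dataset(
            "position", data=np.array([p.position for p in sample.particles],
                                      float).reshape(-1, 3))
        parts.create_dataset(
            "orientation", data=np.array([p.orientation for p in sample.particles],
                                         float).reshape(-1, 4))
        parts.create_dataset(
            "bounding_radius",
            data=np.array([p.bounding_radius for p in sample.particles], float))
        ice = f.create_group("ice")
        ice.attrs["kind"] = sample.ice.kind
        for key, value in sample.ice.model_dump().items():
            if key != "kind":
                ice.attrs[key] = value
        if sample.ice_atoms is not None:
            _write_atoms(ice.create_group("atoms"), sample.ice_atoms)
        if sample.milled_region is not None:
            f.attrs["milled_region"] = sample.milled_region


def sample_load(path: str) -> Sample:
    """Load a sample stored by :func:`sample_store` (schema-checked)."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported sample schema version {version} "
                f"(expected {SCHEMA_VERSION})"
            )
        geometry = _read_geometry(f["geometry"])
        models = {mid: _read_atoms(f["models"][mid]) for mid in f["models"]}
        parts = f["particles"]
        particles = [
            ParticleInstance(
                mid.decode() if isinstance(mid, bytes) else str(mid),
                pos, q, float(r),
            )
            for mid, pos, q, r in zip(
                parts["model_id"][()], parts["position"][()],
                parts["orientation"][()], parts["bounding_radius"][()],
            )
        ]
        ice_grp = f["ice"]
        kind = ice_grp.attrs["kind"]
        attrs = {k: v for k, v in ice_grp.attrs.items() if k != "kind"}
        ice: IceModel
        if kind == "none":
            ice = NoIce()
        elif kind == "random_water":
            ice = RandomWaterIce(density=float(attrs["density"]),
                                 seed=int(attrs["seed"]))
        else:
            ice = GRFIce(
                mean=float(attrs["mean"]), variance=float(attrs["variance"]),
                correlation_length=float(attrs["correlation_length"]),
                seed=int(attrs["seed"]),
            )
        ice_atoms = _read_atoms(ice_grp["atoms"]) if "atoms" in ice_grp else None
        milled = f.attrs.get("milled_region")
        return Sample(geometry=geometry, particles=particles, models=models,
                      ice=ice, ice_atoms=ice_atoms,
                      milled_region=None if milled is None else str(milled))
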