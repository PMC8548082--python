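"""Reconstruction and scoring: close the loop against the ground truth.

CTF correction by phase flipping, weighted back projection (WBP) with a
per-projection weighting filter, per-particle reconstruction with local
defocus correction, wedge-masked subtomogram averaging, and Fourier shell
correlation (FSC) scoring including the element-count-weighted FSC
average and its restriction to reciprocal-space planes.

Volume convention: arrays are indexed ``[z, y, x]``; voxel ``k`` along an
axis of length ``n`` sits at coordinate ``(k - n/2) * voxel_size`` relative
to the volume centre, matching the image-pixel convention of the
simulator.  Fourier arrays use the unshifted (DC-at-[0,0,0]) layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .config import BeamModel, LensModel
from .mrcio import read_mrc, write_mrc
from .sample import AtomicModel, ParticleInstance, rotation_matrix
from .scattering import element_amplitudes
from .simulate import CTF, TiltSeries, ctf_evaluate

__all__ = [
    "Volume",
    "FSCCurve",
    "phase_flip",
    "wbp_weights",
    "wbp_reconstruct",
    "extract_subvolumes",
    "wedge_mask",
    "subtomogram_average",
    "fsc",
    "fsc_average",
    "plane_mask",
    "render_reference_volume",
]


@dataclass
class Volume:
    """Real-space 3D grid with cubic voxels."""

    data: np.ndarray  # (nz, ny, nx)
    voxel_size: float  # A
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # centre, A

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")

    def to_mrc(self, path: str) -> None:
        write_mrc(path, self.data.astype(np.float32), self.voxel_size)

    @classmethod
    def from_mrc(cls, path: str) -> "Volume":
        mrc = read_mrc(path)
        return cls(data=mrc.data, voxel_size=mrc.voxel_size)


@dataclass
class FSCCurve:
    """Per-shell correlation: shell centres (1/A), FSC values and counts.

    Shells without signal (zero power in either input, e.g. the DC shell
    of a filtered reconstruction) carry ``nan`` and are excluded from
    averages along with their element counts.
    """

    q: np.ndarray
    fsc: np.ndarray
    n_elements: np.ndarray

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {"q": self.q, "fsc": self.fsc, "n": self.n_elements}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CTF correction
# ---------------------------------------------------------------------------


def phase_flip(image: np.ndarray, ctf: CTF) -> np.ndarray:
    """Correct CTF contrast inversions by multiplying F[image] by sign(CTF).

    Idempotent up to sign (applying twice is the identity since
    ``sign^2 = 1``); preserves Hermitian symmetry so the output is real.
    """
    image = np.asarray(image)
    if image.shape != ctf.q.shape:
        raise ValueError(
            f"image grid {image.shape} does not match CTF grid {ctf.q.shape}"
        )
    return sp_fft.ifft2(sp_fft.fft2(image) * ctf.sign()).real


# ---------------------------------------------------------------------------
# Weighted back projection
# ---------------------------------------------------------------------------


def wbp_weights(angles_deg: np.ndarray) -> np.ndarray:
    """Per-projection angular weights from the local sampling density.

    Projection directions are taken modulo 180 degrees; each unique
    direction receives half the angular distance to its neighbours
    (nearest-gap rule at the range edges) and exact duplicates share their
    direction's weight equally.  For uniformly spaced projections covering
    180 degrees this reduces to the classical equal-gap ramp weighting.
    Weights are in radians.
    """
    angles = np.asarray(angles_deg, float) % 180.0
    if len(angles) < 2:
        raise ValueError("need at least 2 projections")
    unique, inverse, counts = np.unique(angles, return_inverse=True,
                                        return_counts=True)
    if len(unique) == 1:
        gaps = np.array([math.pi])
    else:
        d = np.diff(unique)
        gaps = np.empty(len(unique))
        gaps[1:-1] = 0.5 * (d[1:] + d[:-1])
        gaps[0] = d[0]
        gaps[-1] = d[-1]
        gaps = np.radians(gaps)
    return gaps[inverse] / counts[inverse]


def _ramp_filter_rows(images: np.ndarray, weights: np.ndarray,
                      pixel_size: float) -> np.ndarray:
    """Weighted ramp filter along x (the axis perpendicular to the tilt axis)."""
    nx = images.shape[-1]
    q = np.abs(np.fft.fftfreq(nx, d=pixel_size))
    spectra = sp_fft.fft(images, axis=-1)
    spectra *= q[None, None, :] * weights[:, None, None]
    return sp_fft.ifft(spectra, axis=-1).real


def wbp_reconstruct(
    images: np.ndarray,
    angles_deg: np.ndarray,
    shape: Tuple[int, int, int],
    pixel_size: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> Volume:
    """Weighted back projection of a (corrected) tilt series.

    Each projection is ramp-filtered along x with its angular weight from
    :func:`wbp_weights` and back-projected with linear interpolation into
    a volume of ``shape`` (nz, ny, nx) voxels centred at ``center``
    (world A); the voxel size equals the image pixel size.
    """
    images = np.asarray(images, float)
    angles = np.asarray(angles_deg, float)
    if images.ndim != 3 or len(images) != len(angles):
        raise ValueError("need one image per angle")
    if len(images) < 2:
        raise ValueError("need at least 2 projections to reconstruct")
    n_img, ny_img, nx_img = images.shape
    weights = wbp_weights(angles)
    filtered = _ramp_filter_rows(images, weights, pixel_size)

    nzv, nyv, nxv = shape
    cx, cy, cz = (np.asarray(center, float)).tolist()
    xs = (np.arange(nxv) - nxv / 2.0) * pixel_size + cx
    ys = (np.arange(nyv) - nyv / 2.0) * pixel_size + cy
    zs = (np.arange(nzv) - nzv / 2.0) * pixel_size + cz
    zg, yg, xg = np.meshgrid(zs, ys, xs, indexing="ij")

    volume = np.zeros(shape)
    v_img = yg / pixel_size + ny_img / 2.0  # y is the tilt axis: constant per image
    for i in range(n_img):
        a = math.radians(angles[i])
        u_img = (xg * math.cos(a) + zg * math.sin(a)) / pixel_size + nx_img / 2.0
        volume += ndimage.map_coordinates(
            filtered[i], [v_img.ravel(), u_img.ravel()], order=1, cval=0.0
        ).reshape(shape)
    return Volume(data=volume, voxel_size=pixel_size,
                  origin=np.array([cx, cy, cz]))


# ---------------------------------------------------------------------------
# Per-particle reconstruction
# ---------------------------------------------------------------------------


def extract_subvolumes(
    tilt_series: TiltSeries,
    particles: Sequence[ParticleInstance],
    box_size: int,
    lens: Optional[LensModel] = None,
    beam: Optional[BeamModel] = None,
    remove_tilt_axis_mean: bool = True,
) -> Tuple[List[Tuple[Volume, ParticleInstance]], int]:
    """Reconstruct each particle independently from the tilt series.

    For every particle (pose known from the ground-truth sample) and every
    projection, a ``box_size`` x ``box_size`` patch centred on the
    particle's projected position is interpolated out of the image,
    converted to fractional contrast against its local mean, phase-flipped
    at the particle-centre defocus (nominal defocus minus the particle's
    beam-axis offset at that tilt) when ``lens``/``beam`` are given, and
    back-projected into a ``box_size^3`` volume.  Particles whose patch
    leaves the image in any projection are skipped and counted.

    ``remove_tilt_axis_mean`` subtracts each patch's mean along the tilt
    axis (y) before back projection: the container body (slab or cylinder)
    is uniform along y, so its projected background is y-invariant and
    would otherwise dominate the ``q_y = 0`` plane of every
    reconstruction.  A reference volume must have its y-mean removed
    before FSC comparison when this normalization is on.

    The fractional-contrast normalization divides each patch by its own
    mean — the per-particle normalization convention of subtomogram
    processing.  On dose-starved projections (heavily attenuated high-tilt
    images) the patch mean is itself Poisson-noisy, so normalization
    amplifies the noise of dark frames; this is part of the modelled
    penalty of high-tilt planar data.

    Returns the (volume, particle) pairs and the skipped-particle count.
    """
    px = tilt_series.pixel_size
    n_img, ny_img, nx_img = tilt_series.images.shape
    b = int(box_size)
    offs = np.arange(b) - b / 2.0
    results: List[Tuple[Volume, ParticleInstance]] = []
    n_skipped = 0

    image_means = tilt_series.images.reshape(n_img, -1).mean(axis=1)

    for particle in particles:
        crops = np.empty((n_img, b, b))
        ok = True
        for i in range(n_img):
            a = math.radians(tilt_series.angles[i])
            c, s = math.cos(a), math.sin(a)
            pos = particle.position
            u_c = (pos[0] * c + pos[2] * s) / px + nx_img / 2.0
            v_c = pos[1] / px + ny_img / 2.0
            if not (b / 2 <= u_c <= nx_img - b / 2 - 1
                    and b / 2 <= v_c <= ny_img - b / 2 - 1):
                ok = False
                break
            uu = u_c + offs
            vv = v_c + offs
            crop = ndimage.map_coordinates(
                tilt_series.images[i].astype(float),
                np.meshgrid(vv, uu, indexing="ij"),
                order=1,
            )
            mean = crop.mean()
            if mean <= 0:
                mean = max(image_means[i], 1e-12)
            contrast = crop / mean - 1.0
            if remove_tilt_axis_mean:
                contrast = contrast - contrast.mean(axis=0, keepdims=True)
            if lens is not None and beam is not None:
                z_rot = -pos[0] * s + pos[2] * c
                ctf = ctf_evaluate(
                    lens, beam, (b, b), px,
                    defocus=tilt_series.defocus[i] - z_rot,
                )
                contrast = phase_flip(contrast, ctf)
            crops[i] = contrast
        if not ok:
            n_skipped += 1
            continue
        vol = wbp_reconstruct(
            crops, tilt_series.angles, (b, b, b), px, center=(0.0, 0.0, 0.0)
        )
        vol.origin = particle.position.copy()
        results.append((vol, particle))
    return results, n_skipped


# ---------------------------------------------------------------------------
# Wedge masks and subtomogram averaging
# ---------------------------------------------------------------------------


def wedge_mask(
    max_tilt_deg: float,
    shape: Tuple[int, int, int],
    soft_deg: float = 0.0,
) -> np.ndarray:
    """Fourier-space sampling mask of a single-axis tilt range about +y.

    An element at frequency ``(qx, qy, qz)`` is sampled iff some tilt in
    ``[-max_tilt, +max_tilt]`` places it on a central section, i.e. iff
    the angle of ``(qx, qz)`` from the x-axis is at most ``max_tilt``
    (independent of ``qy``).  ``soft_deg`` > 0 applies a cosine edge of
    that angular width.  Returned in unshifted FFT layout.
    """
    if not 0.0 < max_tilt_deg <= 90.0:
        raise ValueError(f"max_tilt must be in (0, 90] deg (got {max_tilt_deg})")
    nz, ny, nx = shape
    qx = np.fft.fftfreq(nx)
    qz = np.fft.fftfreq(nz)
    theta = np.degrees(
        np.arctan2(np.abs(qz)[:, None], np.abs(qx)[None, :])
    )  # (nz, nx), angle from the x-axis in the x-z plane
    if soft_deg > 0:
        t = np.clip((max_tilt_deg + soft_deg - theta) / soft_deg, 0.0, 1.0)
        plane = 0.5 - 0.5 * np.cos(math.pi * t)
        plane[theta <= max_tilt_deg] = 1.0
    else:
        plane = (theta <= max_tilt_deg + 1e-9).astype(float)
    return np.broadcast_to(plane[:, None, :], (nz, ny, nx)).copy()


def _rotate_centered(volume: np.ndarray, rot: np.ndarray,
                     order: int = 1) -> np.ndarray:
    """Rotate a real-space volume about its centre by ``rot`` ([z,y,x] data)."""
    # data axes are (z, y, x) but rot acts on (x, y, z): conjugate by reversal
    m = rot[::-1, ::-1]
    center = (np.array(volume.shape) - 1) / 2.0
    m_inv = m.T  # rotation: inverse = transpose
    offset = center - m_inv @ center
    return ndimage.affine_transform(volume, m_inv, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def subtomogram_average(
    volumes: Sequence[Volume],
    particles: Optional[Sequence[ParticleInstance]] = None,
    max_tilt_deg: float = 90.0,
    soft_deg: float = 0.0,
    wiener_floor: float = 1e-3,
) -> Tuple[Volume, Dict[str, float]]:
    """Wedge-masked Fourier average of per-particle reconstructions.

    Each box is rotated to the reference frame by the inverse of its
    particle's orientation (known exactly; no alignment search), its
    Fourier transform is multiplied by the correspondingly rotated missing
    wedge mask, and the masked transforms are summed and divided by the
    summed mask with a Wiener-style floor ``wiener_floor * max(summed
    mask)``.  Fourier regions never covered by any wedge are zero-filled
    and reported in the info dict.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one subvolume to average")
    shape = volumes[0].data.shape
    base_mask = wedge_mask(max_tilt_deg, shape, soft_deg=soft_deg)
    base_mask_shifted = np.fft.fftshift(base_mask)

    numerator = np.zeros(shape, dtype=complex)
    denominator = np.zeros(shape)
    identity = np.array([1.0, 0.0, 0.0, 0.0])
    for i, vol in enumerate(volumes):
        if vol.data.shape != shape:
            raise ValueError("all subvolumes must share one grid")
        if particles is not None:
            q = particles[i].orientation
        else:
            q = identity
        if np.allclose(q, identity):
            data = vol.data
            mask = base_mask
        else:
            rot = rotation_matrix(q)
            data = _rotate_centered(vol.data, rot.T)  # inverse rotation
            mask = np.fft.ifftshift(
                _rotate_centered(base_mask_shifted, rot.T)
            )
        numerator += sp_fft.fftn(data) * mask
        denominator += mask

    floor = wiener_floor * float(denominator.max())
    covered = denominator > floor
    avg_spectrum = np.where(covered, numerator / np.maximum(denominator, floor),
                            0.0)
    average = sp_fft.ifftn(avg_spectrum).real
    info = {
        "coverage_fraction": float(np.mean(covered)),
        "zero_filled_fraction": float(np.mean(~covered)),
    }
    return (
        Volume(data=average, voxel_size=volumes[0].voxel_size,
               origin=np.zeros(3)),
        info,
    )


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------


def _shell_indices(shape: Tuple[int, ...], shell_width: float) -> Tuple[np.ndarray, int]:
    r2 = np.zeros(shape)
    for axis, n in enumerate(shape):
        f = np.fft.fftfreq(n) * n  # frequency in voxel units
        r2 = r2 + f.reshape([-1 if a == axis else 1
                             for a in range(len(shape))]) ** 2
    r = np.sqrt(r2)
    n_shells = int(math.floor(min(shape) / 2 / shell_width)) + 1
    idx = np.floor(r / shell_width).astype(int)
    idx[idx >= n_shells] = -1  # beyond Nyquist sphere: excluded
    return idx, n_shells


def fsc(
    vol_a: Volume | np.ndarray,
    vol_b: Volume | np.ndarray,
    voxel_size: Optional[float] = None,
    shell_width: float = 1.0,
    element_mask: Optional[np.ndarray] = None,
) -> FSCCurve:
    """Fourier shell correlation between two volumes on the same grid.

    ``FSC_i = Re<F_a F_b*>_i / sqrt(<|F_a|^2>_i <|F_b|^2>_i)`` over shells
    of ``shell_width`` frequency voxels, up to the Nyquist sphere.  An
    optional boolean ``element_mask`` (unshifted FFT layout) restricts the
    binned elements, e.g. to a reciprocal-plane slab from
    :func:`plane_mask`.  Zero-power shells are recorded as ``nan``.
    """
    a = vol_a.data if isinstance(vol_a, Volume) else np.asarray(vol_a)
    b = vol_b.data if isinstance(vol_b, Volume) else np.asarray(vol_b)
    if a.shape != b.shape:
        raise ValueError(f"volume grids differ: {a.shape} vs {b.shape}")
    if voxel_size is None:
        voxel_size = vol_a.voxel_size if isinstance(vol_a, Volume) else 1.0
    fa = sp_fft.fftn(a)
    fb = sp_fft.fftn(b)
    idx, n_shells = _shell_indices(a.shape, shell_width)
    sel = idx >= 0
    if element_mask is not None:
        sel = sel & np.asarray(element_mask, bool)
    bins = idx[sel]
    cross = np.bincount(bins, weights=(fa[sel] * np.conj(fb[sel])).real,
                        minlength=n_shells)
    pa = np.bincount(bins, weights=np.abs(fa[sel]) ** 2, minlength=n_shells)
    pb = np.bincount(bins, weights=np.abs(fb[sel]) ** 2, minlength=n_shells)
    counts = np.bincount(bins, minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = cross / np.sqrt(pa * pb)
    values[(pa <= 0) | (pb <= 0)] = np.nan
    n = min(a.shape)
    q = (np.arange(n_shells) + 0.5) * shell_width / (n * voxel_size)
    return FSCCurve(q=q, fsc=values, n_elements=counts)


def plane_mask(
    shape: Tuple[int, int, int], plane: str, slab_deg: float = 15.0
) -> np.ndarray:
    """Elements within ``slab_deg`` of a named reciprocal plane.

    ``plane`` is one of ``"xy"``, ``"xz"``, ``"yz"``; an element qualifies
    when the angle between its frequency vector and the plane is at most
    ``slab_deg`` (the slab convention; declared in output metadata by the
    sweep runner).  The DC element belongs to every plane.
    """
    normals = {"xy": 2, "xz": 1, "yz": 0}
    if plane not in normals:
        raise ValueError(f"plane must be one of {sorted(normals)} (got {plane!r})")
    nz, ny, nx = shape
    fx = np.fft.fftfreq(nx) * nx
    fy = np.fft.fftfreq(ny) * ny
    fz = np.fft.fftfreq(nz) * nz
    comps = [
        np.broadcast_to(fx[None, None, :], shape),
        np.broadcast_to(fy[None, :, None], shape),
        np.broadcast_to(fz[:, None, None], shape),
    ]
    r = np.sqrt(comps[0] ** 2 + comps[1] ** 2 + comps[2] ** 2)
    normal = np.abs(comps[normals[plane]])
    with np.errstate(invalid="ignore", divide="ignore"):
        angle = np.degrees(np.arcsin(np.clip(normal / r, 0.0, 1.0)))
    angle = np.where(r == 0, 0.0, angle)
    return angle <= slab_deg


def fsc_average(
    curve: FSCCurve,
    band: Optional[Tuple[float, float]] = None,
) -> float:
    """Element-count-weighted mean of the FSC over shells.

    ``FSC_avg = sum_i N_i FSC_i / sum_i N_i`` over the defined (non-nan)
    shells, optionally restricted to a resolution band ``(q_min, q_max]``
    in 1/A.  Raises on an empty selection.
    """
    sel = np.isfinite(curve.fsc) & (curve.n_elements > 0)
    if band is not None:
        q_min, q_max = band
        sel &= (curve.q > q_min) & (curve.q <= q_max)
    if not sel.any():
        raise ValueError("empty shell selection for FSC average")
    weights = curve.n_elements[sel]
    return float(np.sum(weights * curve.fsc[sel]) / np.sum(weights))


# ---------------------------------------------------------------------------
# Reference (ground-truth) density
# ---------------------------------------------------------------------------


def render_reference_volume(
    atoms: AtomicModel,
    box_size: int,
    voxel_size: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> Volume:
    """Render an atomic model into a 3D potential volume (V).

    Uses the same per-element Gaussian potential parameterization as the
    image simulator, so reconstructions and references differ only by the
    transfer of the imaging pipeline.  ``center`` is the world-coordinate
    centre of the box.
    """
    b = int(box_size)
    vol = np.zeros((b, b, b))
    if atoms.n_atoms == 0:
        return Volume(vol, voxel_size, np.asarray(center, float))
    amps, widths = element_amplitudes(atoms.elements)
    c_eff = np.sqrt(widths**2 + (0.5 * voxel_size) ** 2)
    peak = amps * atoms.occupancy / ((2.0 * math.pi) ** 1.5 * c_eff**3)

    rel = (atoms.coords - np.asarray(center, float)) / voxel_size + b / 2.0
    p = int(np.ceil(4.0 * c_eff.max() / voxel_size))
    offs = np.arange(-p, p + 1)
    base = np.round(rel).astype(int)

    inside = np.all((rel >= -p) & (rel < b + p), axis=1)
    rel, base, peak, c_eff = rel[inside], base[inside], peak[inside], c_eff[inside]
    if len(rel) == 0:
        return Volume(vol, voxel_size, np.asarray(center, float))

    inv2c2 = (voxel_size**2) / (2.0 * c_eff**2)
    gs = []
    idxs = []
    oks = []
    for axis in range(3):
        d = (base[:, axis][:, None] + offs[None, :]) - rel[:, axis][:, None]
        gs.append(np.exp(-(d**2) * inv2c2[:, None]))
        ii = base[:, axis][:, None] + offs[None, :]
        oks.append((ii >= 0) & (ii < b))
        idxs.append(np.clip(ii, 0, b - 1))
    vals = (
        peak[:, None, None, None]
        * gs[2][:, :, None, None]  # z
        * gs[1][:, None, :, None]  # y
        * gs[0][:, None, None, :]  # x
        * (oks[2][:, :, None, None] & oks[1][:, None, :, None]
           & oks[0][:, None, None, :])
    )
    flat = (
        idxs[2][:, :, None, None] * (b * b)
        + idxs[1][:, None, :, None] * b
        + idxs[0][:, None, None, :]
    )
    np.add.at(vol.reshape(-1), np.broadcast_to(flat, vals.shape).ravel(),
              vals.ravel())
    return Volume(vol, voxel_size, np.asarray(center, float))
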