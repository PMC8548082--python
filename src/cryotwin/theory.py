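"""Closed-form geometry and sampling formulas for single-axis tomography.

These are the analytic relations used to interpret the in-silico
experiments: the projected-thickness increase of a tilted slab, the
corresponding intensity loss through inelastic scattering, the Crowther
resolution criterion, and the missing-wedge opening angle of a limited
tilt range.

Symbol note: the inelastic mean free path is named ``lambda_in``
(:math:`\\Lambda_{in}`) throughout to avoid a collision with the electron
wavelength :math:`\\lambda_e` used by the image simulator.
"""

from __future__ import annotations

import math

__all__ = [
    "relative_thickness",
    "relative_intensity",
    "crowther_resolution",
    "missing_wedge_angle",
]


def relative_thickness(tilt_deg: float) -> float:
    """Projected thickness of a planar slab at tilt, relative to zero tilt.

    For a lamella of zero-tilt thickness ``D0`` tilted by ``alpha`` about an
    in-plane axis, the path length of the beam through the slab is
    ``D = D0 / cos(alpha)``.

    Parameters
    ----------
    tilt_deg:
        Tilt angle in degrees; must satisfy ``|tilt| < 90`` (at 90 degrees a
        planar slab is edge-on and the formula diverges).

    Returns
    -------
    float
        ``D / D0 = 1 / cos(alpha)``.
    """
    if abs(tilt_deg) >= 90.0:
        raise ValueError(
            f"relative_thickness undefined for |tilt| >= 90 deg (got {tilt_deg})"
        )
    return 1.0 / math.cos(math.radians(tilt_deg))


def relative_intensity(tilt_deg: float, d0: float, lambda_in: float) -> float:
    """Unscattered (zero-loss) intensity of a tilted slab relative to zero tilt.

    Beer--Lambert attenuation with the inelastic mean free path
    ``lambda_in`` gives ``I/I0 = exp((1 - 1/cos(alpha)) * D0 / lambda_in)``.
    ``d0`` and ``lambda_in`` may be in any common length unit.

    Parameters
    ----------
    tilt_deg:
        Tilt angle in degrees, ``|tilt| < 90``.
    d0:
        Zero-tilt slab thickness (> 0).
    lambda_in:
        Inelastic mean free path (> 0), same unit as ``d0``.
    """
    if d0 <= 0:
        raise ValueError(f"d0 must be > 0 (got {d0})")
    if lambda_in <= 0:
        raise ValueError(f"lambda_in must be > 0 (got {lambda_in})")
    return math.exp((1.0 - relative_thickness(tilt_deg)) * d0 / lambda_in)


def crowther_resolution(diameter: float, n_projections: int) -> float:
    """Crowther criterion: resolution achievable from ``N`` projections.

    ``d = pi * D / N`` for an object of diameter ``D`` sampled by ``N``
    equally spaced projections filling Fourier space, ignoring symmetry and
    detector sampling limits.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0 (got {diameter})")
    if n_projections < 1:
        raise ValueError(f"n_projections must be >= 1 (got {n_projections})")
    return math.pi * diameter / n_projections


def missing_wedge_angle(max_tilt_deg: float) -> float:
    """Opening angle (degrees) of the missing wedge for a tilt range of ±max_tilt.

    A single-axis series over ``(-alpha_max, +alpha_max)`` leaves a wedge of
    ``180 - 2 * alpha_max`` degrees of Fourier-space directions unsampled.
    """
    if not 0.0 < max_tilt_deg <= 90.0:
        raise ValueError(f"max_tilt must be in (0, 90] deg (got {max_tilt_deg})")
    return 180.0 - 2.0 * max_tilt_deg
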