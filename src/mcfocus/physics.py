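"""Scalar single-photon physics: step sampling, Henyey-Greenstein spin,
Fresnel/Snell boundary relations.

All functions here are ``numba.njit``-compiled scalars shared by the Python
API (thin wrappers drawing deviates from a ``numpy.random.Generator``) and
the compiled transport kernel, so there is a single source of truth for the
formulas. Angles are handled through their cosines wherever possible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "sample_step",
    "hg_cos_theta",
    "spin_hg",
    "specular_reflectance",
    "critical_angle",
    "refraction_angle",
    "fresnel_unpolarized",
    "rotate_direction",
    "isotropic_direction",
]

#: direction cosines are renormalised when their norm drifts beyond this
_COS_NORM_TOL = 1e-12


@njit(cache=True)
def _step_from_deviate(xi: float, mu_t: float) -> float:
    # xi in (0, 1]; s = -ln(xi)/mu_t, the exponential free path
    return -math.log(xi) / mu_t


def sample_step(rng: np.random.Generator, mu_t: float) -> float:
    """Draw an exponential free-path length (cm) for total attenuation
    ``mu_t`` (cm^-1). Raises for non-positive ``mu_t``: a vacuum guard layer
    is traversed ballistically by the transport loop, never sampled."""
    if mu_t <= 0.0:
        raise ValueError("mu_t must be > 0; vacuum layers are ballistic")
    # 1 - U in [“(0, 1]”) so log() never sees zero
    xi = 1.0 - rng.random()
    return _step_from_deviate(xi, mu_t)


@njit(cache=True)
def hg_cos_theta(g: float, xi: float) -> float:
    """Henyey-Greenstein polar-deflection cosine for anisotropy ``g`` and a
    uniform deviate ``xi`` in [0, 1). ``g = 0`` falls back to the isotropic
    form; ``|g| = 1`` is deterministic forward/backward."""
    if g >= 1.0:
        return 1.0
    if g <= -1.0:
        return -1.0
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


def spin_hg(rng: np.random.Generator, g: float) -> tuple[float, float]:
    """Sample a scattering event: (cos(theta), psi) with psi uniform on
    [0, 2*pi) and cos(theta) Henyey-Greenstein distributed."""
    if not -1.0 <= g <= 1.0:
        raise ValueError("anisotropy g must lie in [-1, 1]")
    ct = hg_cos_theta(g, rng.random())
    psi = 2.0 * math.pi * rng.random()
    return ct, psi


@njit(cache=True)
def specular_reflectance(n1: float, n2: float) -> float:
    """Normal-incidence Fresnel reflectance ((n1-n2)/(n1+n2))^2."""
    r = (n1 - n2) / (n1 + n2)
    return r * r


def critical_angle(n1: float, n2: float) -> float | None:
    """Critical angle (radians) for light going from index ``n1`` to ``n2``,
    or ``None`` when total internal reflection is impossible (n2 >= n1)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    if n2 >= n1:
        return None
    return math.asin(n2 / n1)


def refraction_angle(n1: float, n2: float, alpha: float) -> float:
    """Snell refraction angle beta = asin((n1/n2) sin(alpha)) in radians.

    Raises ``ValueError`` when ``alpha`` is at or beyond the critical angle:
    the caller must reflect instead.
    """
    s = (n1 / n2) * math.sin(alpha)
    if s > 1.0:
        raise ValueError("incidence beyond the critical angle: reflect")
    return math.asin(s)


@njit(cache=True)
def fresnel_unpolarized(n1: float, n2: float, cos_ai: float) -> tuple[float, float]:
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_ai`` at an
    ``n1 -> n2`` interface.

    Returns ``(R, cos_at)`` with ``cos_at`` the transmission-angle cosine
    (0 under total internal reflection, where R = 1). Grazing incidence and
    matched indices are handled without division by zero.
    """
    if cos_ai > 1.0:
        cos_ai = 1.0
    if n1 == n2:
        return 0.0, cos_ai
    if cos_ai > 1.0 - 1e-12:  # normal incidence
        return specular_reflectance(n1, n2), 1.0
    if cos_ai < 1e-6:  # grazing
        return 1.0, 0.0
    sin_ai = math.sqrt(1.0 - cos_ai * cos_ai)
    sin_at = sin_ai * n1 / n2
    if sin_at >= 1.0:  # total internal reflection
        return 1.0, 0.0
    cos_at = math.sqrt(1.0 - sin_at * sin_at)
    # average of s- and p-polarised reflectances, in the compact
    # sin/tan-free form used by MCML
    cap = cos_ai * cos_at - sin_ai * sin_at  # cos(ai + at)
    cam = cos_ai * cos_at + sin_ai * sin_at  # cos(ai - at)
    sap = sin_ai * cos_at + cos_ai * sin_at  # sin(ai + at)
    sam = sin_ai * cos_at - cos_ai * sin_at  # sin(ai - at)
    r = 0.5 * sam * sam * (cam * cam + cap * cap) / (sap * sap * cam * cam)
    if r > 1.0:
        r = 1.0
    elif r < 0.0:
        r = 0.0
    return r, cos_at


@njit(cache=True)
def rotate_direction(
    ux: float, uy: float, uz: float, cos_t: float, psi: float
) -> tuple[float, float, float]:
    """Rotate a unit direction by polar deflection ``cos_t`` and azimuth
    ``psi`` (standard MCML update; near-vertical handled separately)."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(psi)
    sin_p = math.sin(psi)
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t if uz >= 0.0 else -cos_t
    else:
        denom = math.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
        nuz = -sin_t * cos_p * denom + uz * cos_t
    norm2 = nux * nux + nuy * nuy + nuz * nuz
    if abs(norm2 - 1.0) > _COS_NORM_TOL:
        inv = 1.0 / math.sqrt(norm2)
        nux *= inv
        nuy *= inv
        nuz *= inv
    return nux, nuy, nuz


@njit(cache=True)
def _isotropic_from_deviates(xi1: float, xi2: float) -> tuple[float, float, float]:
    uz = 2.0 * xi1 - 1.0
    psi = 2.0 * math.pi * xi2
    s = math.sqrt(max(0.0, 1.0 - uz * uz))
    return s * math.cos(psi), s * math.sin(psi), uz


def isotropic_direction(rng: np.random.Generator) -> tuple[float, float, float]:
    """Uniform direction on the unit sphere (fluorescence emission)."""
    return _isotropic_from_deviates(rng.random(), rng.random())
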