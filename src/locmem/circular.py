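"""Circular arithmetic and von Mises distribution machinery.

Every angle that crosses the public API is in degrees; radians appear only
inside function bodies.  Densities are expressed *per degree* so that mixture
weights remain unit-free when a uniform-on-the-circle component (density
1/360 per degree) is combined with von Mises components.

The von Mises concentration parameter ``kappa`` and the circular standard
deviation are linked bijectively through the Bessel-function ratio
``R(kappa) = I1(kappa) / I0(kappa)``::

    circ_sd (radians) = sqrt(-2 * ln R(kappa))

Higher ``kappa`` means a tighter response distribution (smaller SD); the
two parametrisations are interchangeable ways of expressing localization
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.stats import vonmises as _vonmises

__all__ = [
    "CircularDispersion",
    "wrap_angle",
    "signed_error",
    "vm_density",
    "vm_mass",
    "bessel_ratio",
    "kappa_to_circ_sd",
    "circ_sd_to_kappa",
    "kappa_sd_convert",
]

#: kappa below this is treated as exactly uniform in mass computations.
_KAPPA_UNIFORM_EPS = 1e-12

#: bracket for the numerical kappa <- SD inversion, in log(kappa) units.
_LOG_KAPPA_BRACKET = (-30.0, 35.0)


def _as_finite_array(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def wrap_angle(angle_deg):
    """Wrap an angle (or array of angles) to the interval (-180, 180].

    The convention maps -180 to +180, so every angle has a unique signed
    representative.  Scalars in give scalars out.
    """
    arr = _as_finite_array("angle_deg", angle_deg)
    wrapped = np.mod(arr, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    if np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def signed_error(response_deg, target_deg):
    """Signed localization error: response minus target, wrapped to (-180, 180].

    Positive values mean the response fell counter-clockwise of the target;
    the mixture models are symmetric so only downstream delay and
    nearest-neighbour analyses rely on the sign convention being consistent.
    """
    resp = _as_finite_array("response_deg", response_deg)
    targ = _as_finite_array("target_deg", target_deg)
    return wrap_angle(resp - targ)


def vm_density(theta_deg, mu_deg, kappa):
    """von Mises probability density per degree at ``theta_deg``.

    ``f(theta) = exp(kappa * cos(theta - mu)) / (360 * I0(kappa))`` with the
    cosine evaluated in radians.  At ``kappa = 0`` this is the uniform density
    1/360.  Implemented with exponentially scaled Bessel functions so large
    concentrations do not overflow.
    """
    k = float(kappa)
    if not np.isfinite(k) or k < 0:
        raise ValueError(f"kappa must be finite and >= 0, got {kappa!r}")
    theta = _as_finite_array("theta_deg", theta_deg)
    mu = _as_finite_array("mu_deg", mu_deg)
    delta = np.radians(theta - mu)
    dens = np.exp(k * (np.cos(delta) - 1.0)) / (360.0 * special.i0e(k))
    if np.ndim(theta_deg) == 0 and np.ndim(mu_deg) == 0:
        return float(dens)
    return dens


def vm_mass(half_width_deg, kappa):
    """Probability a von Mises variate falls within +/- ``half_width_deg`` of its mean."""
    hw = float(half_width_deg)
    if hw < 0:
        raise ValueError("half_width_deg must be >= 0")
    hw = min(hw, 180.0)
    k = float(kappa)
    if k < 0:
        raise ValueError("kappa must be >= 0")
    if k < _KAPPA_UNIFORM_EPS:
        return 2.0 * hw / 360.0
    hw_rad = np.radians(hw)
    return float(_vonmises.cdf(hw_rad, k) - _vonmises.cdf(-hw_rad, k))


def bessel_ratio(kappa):
    """Mean resultant length R(kappa) = I1(kappa) / I0(kappa)."""
    k = np.asarray(kappa, dtype=float)
    r = special.i1e(k) / special.i0e(k)
    if np.ndim(kappa) == 0:
        return float(r)
    return r


def kappa_to_circ_sd(kappa: float) -> float:
    """Circular standard deviation in degrees for a given concentration.

    Returns ``inf`` when kappa is so small that the distribution is
    effectively uniform (the circular SD is unbounded in that limit).
    """
    k = float(kappa)
    if not np.isfinite(k) or k < 0:
        raise ValueError(f"kappa must be finite and >= 0, got {kappa!r}")
    r = bessel_ratio(k)
    if r <= 0.0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def circ_sd_to_kappa(circ_sd_deg: float) -> float:
    """Invert the kappa -> circular-SD map numerically.

    Solves ``I1(k)/I0(k) = exp(-sd_rad**2 / 2)`` for ``k`` by bracketed
    root-finding on log(kappa); the map is strictly monotone so the root is
    unique.  The root itself is located to near machine precision; a guard
    raises ``RuntimeError`` if the round-trip fails to reproduce the input to
    1e-6 relative accuracy (the evaluation-noise floor of the Bessel ratio at
    extreme concentrations).
    """
    sd = float(circ_sd_deg)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"circ_sd_deg must be finite and > 0, got {circ_sd_deg!r}")
    target_r = float(np.exp(-0.5 * np.radians(sd) ** 2))

    def f(log_k):
        return bessel_ratio(np.exp(log_k)) - target_r

    lo, hi = _LOG_KAPPA_BRACKET
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(f"kappa inversion bracket failed for circ_sd={sd}")
    log_k = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    kappa = float(np.exp(log_k))
    back = kappa_to_circ_sd(kappa)
    if not np.isclose(back, sd, rtol=1e-6, atol=0.0):
        raise RuntimeError(
            f"kappa inversion did not converge: sd={sd} -> kappa={kappa} -> sd={back}"
        )
    return kappa


@dataclass(frozen=True)
class CircularDispersion:
    """A concentration / circular-SD pair describing one von Mises spread.

    The two fields always satisfy ``circ_sd_deg == kappa_to_circ_sd(kappa)``;
    construct through :meth:`from_kappa` or :meth:`from_circ_sd` to keep the
    invariant.
    """

    kappa: float
    circ_sd_deg: float

    @classmethod
    def from_kappa(cls, kappa: float) -> "CircularDispersion":
        if not np.isfinite(kappa) or kappa <= 0:
            raise ValueError(f"kappa must be finite and > 0, got {kappa!r}")
        return cls(kappa=float(kappa), circ_sd_deg=kappa_to_circ_sd(kappa))

    @classmethod
    def from_circ_sd(cls, circ_sd_deg: float) -> "CircularDispersion":
        return cls(kappa=circ_sd_to_kappa(circ_sd_deg), circ_sd_deg=float(circ_sd_deg))


def kappa_sd_convert(value: float, direction: str) -> CircularDispersion:
    """Convert between concentration and circular SD.

    Parameters
    ----------
    value:
        The known quantity (must be > 0).
    direction:
        ``"kappa_to_sd"`` when ``value`` is a concentration, ``"sd_to_kappa"``
        when it is a circular SD in degrees.
    """
    if direction == "kappa_to_sd":
        return CircularDispersion.from_kappa(value)
    if direction == "sd_to_kappa":
        return CircularDispersion.from_circ_sd(value)
    raise ValueError(
        f"direction must be 'kappa_to_sd' or 'sd_to_kappa', got {direction!r}"
    )
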