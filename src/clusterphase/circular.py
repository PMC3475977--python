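"""Circular-arithmetic primitives shared by every synchrony statistic.

All phase statistics in this package reduce to operations on unit vectors
``exp(i*angle)``: the cluster phase is the argument of a mean unit vector,
and every synchrony degree (individual, group, dyadic) is a mean resultant
length.  Keeping these two primitives in one place guarantees that every
module uses the same wrapping convention and the same degeneracy rule.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEGENERACY_TOL",
    "wrap_angle",
    "circular_mean_and_resultant",
    "circular_sd",
]

#: Resultant moduli below this are treated as degenerate: the mean direction
#: of a set of (near-)cancelling unit vectors is mathematically undefined and
#: the two-argument arctangent of (~0, ~0) would return an arbitrary angle.
DEGENERACY_TOL = 1e-9


def wrap_angle(angle):
    """Wrap angles to the interval ``(-pi, pi]``.

    The branch cut resolves ``+pi -> +pi``; values strictly above ``pi``
    wrap negative (so ``3*pi -> pi`` and ``-5*pi/2 -> -pi/2``).  Any
    consistent convention would do because downstream statistics act on
    unit vectors, but one convention is enforced everywhere.

    Parameters
    ----------
    angle : float or array-like
        Angle(s) in radians; must be finite.

    Returns
    -------
    float or ndarray
        ``angle`` reduced modulo ``2*pi`` into ``(-pi, pi]``.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.pi - np.mod(np.pi - a, 2.0 * np.pi)
    if np.isscalar(angle) or a.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_mean_and_resultant(angles):
    """Mean direction and mean resultant length of a set of angles.

    Computes the complex mean ``m = mean(exp(i*angles))``; the resultant
    length is ``|m|`` (in ``[0, 1]``) and the mean direction is ``arg(m)``
    via the two-argument arctangent.  The resultant length is 1 iff all
    angles coincide (mod 2*pi) and 0 when the unit vectors cancel.

    Returns
    -------
    mean_direction : float
        Mean angle in ``(-pi, pi]``; ``nan`` when the resultant modulus is
        below :data:`DEGENERACY_TOL` (direction undefined).
    resultant_length : float
        Modulus of the complex mean, clipped to ``[0, 1]``.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean_and_resultant requires a non-empty sequence")
    if not np.all(np.isfinite(a)):
        raise ValueError("circular_mean_and_resultant requires finite angles")
    m = np.exp(1j * a).mean()
    r = min(float(np.abs(m)), 1.0)
    if r < DEGENERACY_TOL:
        return float("nan"), r
    return float(np.arctan2(m.imag, m.real)), r


def circular_sd(resultant_length: float) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` in radians.

    Standard directional-statistics dispersion for a mean resultant length
    ``R``; 0 for perfect concentration, unbounded as ``R -> 0``.
    """
    r = float(resultant_length)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"resultant length must be in [0, 1], got {r}")
    if r == 0.0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(r)))
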