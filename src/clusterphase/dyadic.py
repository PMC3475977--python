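"""Pairwise (dyadic) synchrony between all participant pairs.

For each unordered pair the dyadic relative phase is
``phi_d(t_i) = theta_a(t_i) - theta_b(t_i)``; the dyadic synchrony degree
``rho_d`` is its mean resultant length and ``phi_bar_d`` its circular mean.
Dyadic synchrony measures how tightly two particular members lock to each
other in isolation; it is deliberately distinct from the group statistic —
a group can show high mean dyadic synchrony without a coherent group-level
cluster.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .circular import circular_mean_and_resultant, wrap_angle
from .datatypes import DyadicSynchronyMatrix, PhaseTimeSeries, ValidationError

__all__ = ["dyadic_sync", "dyadic_matrix", "DyadicSynchronyAnalyzer"]


def dyadic_sync(theta_a, theta_b) -> tuple:
    """Dyadic synchrony for one pair of phase time-series.

    Returns ``(rho_d, phi_bar_d)``: the mean resultant length and circular
    mean of ``wrap(theta_a - theta_b)``.  ``rho_d = 1`` iff the two series
    differ by a constant offset (then ``phi_bar_d`` equals that offset);
    ``rho_d = 0`` when the relative phase is uniformly spread.
    """
    a = np.asarray(theta_a, dtype=float).ravel()
    b = np.asarray(theta_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    phi_d = wrap_angle(a - b)
    phi_bar_d, rho_d = circular_mean_and_resultant(phi_d)
    return rho_d, phi_bar_d


def dyadic_matrix(theta) -> DyadicSynchronyMatrix:
    """All-pairs dyadic synchrony matrix.

    The ``rho_d`` matrix is symmetric with unit diagonal; ``phi_bar_d`` is
    antisymmetric off-diagonal (``phi_bar_d[b, a] = -phi_bar_d[a, b]``
    mod 2*pi) and ``nan`` where the mean direction is degenerate.
    """
    if isinstance(theta, PhaseTimeSeries):
        phases, labels = theta.phases, theta.labels
    else:
        phases = np.asarray(theta, dtype=float)
        labels = ()
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValidationError("dyadic_matrix needs a 2-D phase array with n >= 2 rows")
    n = phases.shape[0]
    rho = np.eye(n)
    phi = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            rho_d, phi_bar_d = dyadic_sync(phases[a], phases[b])
            rho[a, b] = rho[b, a] = rho_d
            phi[a, b] = phi_bar_d
            phi[b, a] = wrap_angle(-phi_bar_d) if np.isfinite(phi_bar_d) else float("nan")
    return DyadicSynchronyMatrix(rho_d=rho, phi_bar_d=phi, labels=labels)


class DyadicSynchronyAnalyzer(BaseEstimator):
    """Estimator computing the all-pairs dyadic synchrony matrix.

    Accepts in :meth:`fit` a :class:`PhaseTimeSeries` or a plain
    ``(n_samples, n_participants)`` array of wrapped phases.

    Attributes (after ``fit``)
    --------------------------
    rho_d_ : (n, n) ndarray — symmetric pairwise synchrony, unit diagonal
    phi_bar_d_ : (n, n) ndarray — mean dyadic relative phase, radians
    matrix_ : DyadicSynchronyMatrix
    """

    def fit(self, X, y=None):
        theta = X if isinstance(X, PhaseTimeSeries) else np.asarray(X, dtype=float).T
        self.matrix_ = dyadic_matrix(theta)
        self.rho_d_ = self.matrix_.rho_d
        self.phi_bar_d_ = self.matrix_.phi_bar_d
        return self
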