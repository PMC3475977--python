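"""Cluster-phase statistics: group, individual, and continuous synchrony.

The statistic treats every participant's instantaneous phase as a unit
vector.  The *cluster phase* ``q(t_i)`` is the argument of the mean unit
vector across participants — the group's central phase, the direct analogue
of the Kuramoto order-parameter phase.  Each participant's *relative phase*
``phi_k = theta_k - q`` measures their position with respect to the group;
its circular mean ``phi_bar_k`` is the participant's stable offset and its
mean resultant length ``rho_k`` their degree of synchrony to the group
(1 = phase-locked to the cluster up to a constant, 0 = unrelated).

The continuous group synchrony ``rho_group_i`` is the resultant length, at
each time step, of the offset-corrected relative phases
``phi_k(t_i) - phi_bar_k``; its time average ``rho_group`` is the
trial-level degree of group synchronisation.  Subtracting ``phi_bar_k``
means a group locked in any fixed phase pattern (not just inphase) scores
``rho_group = 1``.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .circular import DEGENERACY_TOL, circular_mean_and_resultant, wrap_angle
from .datatypes import (
    ClusterPhaseResult,
    DegeneracyError,
    MovementTimeSeries,
    PhaseTimeSeries,
    ValidationError,
)

__all__ = [
    "cluster_phase",
    "relative_phase",
    "individual_sync",
    "group_sync",
    "analyze_trial",
    "ClusterPhaseAnalyzer",
]

logger = logging.getLogger(__name__)


def _phases_of(theta) -> np.ndarray:
    if isinstance(theta, PhaseTimeSeries):
        return theta.phases
    arr = np.asarray(theta, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("phase input must be a 2-D (participants x samples) array")
    return arr


def cluster_phase(theta) -> tuple:
    """Cluster phase q(t_i): argument of the mean unit vector across rows.

    Returns
    -------
    q : (N,) ndarray
        Cluster phase in (-pi, pi].  At degenerate steps the arbitrary
        arctangent output is kept but flagged.
    degenerate_mask : (N,) ndarray of bool
        True where the mean-vector modulus is below the degeneracy
        tolerance (phases cancel; q is mathematically undefined there).
    """
    phases = _phases_of(theta)
    if phases.shape[0] < 2:
        raise ValidationError(f"cluster phase needs n >= 2 participants, got {phases.shape[0]}")
    if not np.all(np.isfinite(phases)):
        raise ValidationError("cluster phase requires finite phases")
    mean_vec = np.exp(1j * phases).mean(axis=0)
    q = np.arctan2(mean_vec.imag, mean_vec.real)
    degenerate = np.abs(mean_vec) < DEGENERACY_TOL
    return q, degenerate


def relative_phase(theta, q) -> np.ndarray:
    """Relative phases phi_k(t_i) = wrap(theta_k(t_i) - q(t_i))."""
    phases = _phases_of(theta)
    q = np.asarray(q, dtype=float)
    if q.shape != (phases.shape[1],):
        raise ValidationError(f"q has shape {q.shape}, expected ({phases.shape[1]},)")
    return wrap_angle(phases - q[np.newaxis, :])


def individual_sync(phi_row, retain_mask=None) -> tuple:
    """Mean relative phase and synchrony degree for one participant.

    Returns ``(phi_bar, rho_k)`` — the circular mean and mean resultant
    length of the relative-phase row.  ``phi_bar`` is ``nan`` when the
    resultant is degenerate (uniformly spread relative phase).  An optional
    boolean ``retain_mask`` restricts the time steps entering the average
    (used to drop degenerate cluster-phase steps).
    """
    row = np.asarray(phi_row, dtype=float).ravel()
    if retain_mask is not None:
        row = row[np.asarray(retain_mask, dtype=bool)]
    if row.size == 0:
        raise ValidationError("individual_sync: no retained time steps")
    return circular_mean_and_resultant(row)


def group_sync(phi, phi_bar, retain_mask=None, undefined_phi_bar: str = "zero") -> tuple:
    """Continuous and trial-level group synchrony.

    ``rho_group_t[i]`` is the resultant length of
    ``phi_k(t_i) - phi_bar_k`` across participants; ``rho_group`` is its
    arithmetic mean over retained steps.

    An undefined (nan) ``phi_bar_k`` — a participant with uniformly spread
    relative phase — is handled per ``undefined_phi_bar``: ``"zero"``
    (default) substitutes 0 with a logged warning, which perturbs
    ``rho_group_t`` by at most ``1/n``; ``"error"`` raises.
    """
    phi = np.asarray(phi, dtype=float)
    phi_bar = np.asarray(phi_bar, dtype=float)
    if phi.ndim != 2 or phi_bar.shape != (phi.shape[0],):
        raise ValidationError(
            f"shape mismatch: phi {phi.shape}, phi_bar {phi_bar.shape}; expected (n, N) and (n,)"
        )
    undefined = ~np.isfinite(phi_bar)
    if undefined.any():
        if undefined_phi_bar == "error":
            raise DegeneracyError(
                f"phi_bar undefined for participant(s) {np.flatnonzero(undefined).tolist()}; "
                "re-run with undefined_phi_bar='zero' to substitute a zero offset"
            )
        if undefined_phi_bar != "zero":
            raise ValidationError(f"undefined_phi_bar must be 'zero' or 'error', got {undefined_phi_bar!r}")
        logger.warning(
            "phi_bar undefined for participant(s) %s (uniform relative phase); "
            "substituting 0 — rho_group_t changes by at most 1/n",
            np.flatnonzero(undefined).tolist(),
        )
        phi_bar = np.where(undefined, 0.0, phi_bar)
    vec = np.exp(1j * (phi - phi_bar[:, np.newaxis])).mean(axis=0)
    rho_group_t = np.minimum(np.abs(vec), 1.0)
    if retain_mask is not None:
        retained = rho_group_t[np.asarray(retain_mask, dtype=bool)]
        if retained.size == 0:
            raise ValidationError("group_sync: no retained time steps")
    else:
        retained = rho_group_t
    return rho_group_t, float(retained.mean())


def _compute_result(
    theta: PhaseTimeSeries,
    degenerate_policy: str = "exclude",
    undefined_phi_bar: str = "zero",
    mean_frequency_hz: float | None = None,
) -> ClusterPhaseResult:
    """Steps 2-5 from an already-extracted phase time-series."""
    if degenerate_policy not in ("exclude", "include", "error"):
        raise ValidationError(
            f"degenerate_policy must be 'exclude', 'include' or 'error', got {degenerate_policy!r}"
        )
    q, degenerate = cluster_phase(theta)
    if degenerate.any() and degenerate_policy == "error":
        raise DegeneracyError(
            f"{int(degenerate.sum())} time step(s) have a degenerate cluster phase "
            "(participant phases cancel); choose policy 'exclude' or 'include'"
        )
    retain = ~degenerate if (degenerate_policy == "exclude" and degenerate.any()) else None
    phi = relative_phase(theta, q)
    n = phi.shape[0]
    phi_bar = np.empty(n)
    rho_k = np.empty(n)
    for k in range(n):
        phi_bar[k], rho_k[k] = individual_sync(phi[k], retain_mask=retain)
    rho_group_t, rho_group = group_sync(phi, phi_bar, retain_mask=retain, undefined_phi_bar=undefined_phi_bar)
    return ClusterPhaseResult(
        q=q,
        phi=phi,
        phi_bar=phi_bar,
        rho_k=rho_k,
        rho_group_t=rho_group_t,
        rho_group=rho_group,
        degenerate_mask=degenerate,
        sample_rate=theta.sample_rate,
        labels=theta.labels,
        mean_frequency_hz=mean_frequency_hz,
    )


def analyze_trial(
    x: MovementTimeSeries,
    preprocess_config=None,
    phase_method: str = "hilbert",
    degenerate_policy: str = "exclude",
    undefined_phi_bar: str = "zero",
) -> ClusterPhaseResult:
    """Full per-trial pipeline: condition -> phase -> cluster statistics.

    Runs the conditioning chain (downsample, centre, low-pass, optional
    trim), extracts instantaneous phases by ``phase_method``, and computes
    all cluster-phase statistics.  Also estimates the trial's mean movement
    frequency by peak picking on the conditioned signals.

    Errors from each stage propagate with a stage label prefixed.
    """
    from .phase import extract_phase
    from .preprocess import PreprocessConfig, estimate_frequency_peaks
    from .preprocess import preprocess as run_preprocess

    cfg = preprocess_config or PreprocessConfig()
    try:
        conditioned = run_preprocess(x, cfg)
    except (ValidationError, DegeneracyError) as exc:
        raise type(exc)(f"[preprocess] {exc}") from exc
    freqs = []
    for row in conditioned.values:
        try:
            freqs.append(estimate_frequency_peaks(row, conditioned.sample_rate))
        except DegeneracyError:
            pass
    mean_freq = float(np.mean(freqs)) if freqs else None
    try:
        theta = extract_phase(conditioned, phase_method)
    except (ValidationError, DegeneracyError) as exc:
        raise type(exc)(f"[phase] {exc}") from exc
    try:
        return _compute_result(
            theta,
            degenerate_policy=degenerate_policy,
            undefined_phi_bar=undefined_phi_bar,
            mean_frequency_hz=mean_freq,
        )
    except (ValidationError, DegeneracyError) as exc:
        raise type(exc)(f"[cluster] {exc}") from exc


class ClusterPhaseAnalyzer(BaseEstimator):
    """Estimator computing all cluster-phase synchrony statistics for a trial.

    Accepts in :meth:`fit` either a :class:`PhaseTimeSeries`, a plain
    ``(n_samples, n_participants)`` array of wrapped phases (sklearn
    orientation), or — when ``from_displacement=True`` — a
    :class:`MovementTimeSeries` to be conditioned and phase-extracted
    internally.

    Parameters
    ----------
    degenerate_policy : {"exclude", "include", "error"}
        What to do with time steps whose cluster phase is degenerate
        (participant phases cancel): drop them from the time averages
        (default), keep them, or raise.
    undefined_phi_bar : {"zero", "error"}
        Fallback for a participant whose mean relative phase is undefined.
    from_displacement : bool
        Treat the input as raw displacement and run the full pipeline.
    phase_method, preprocess_config
        Forwarded to the pipeline when ``from_displacement`` is true.

    Attributes (after ``fit``)
    --------------------------
    cluster_phase_ : (N,) ndarray — q(t_i)
    relative_phase_ : (n, N) ndarray — phi_k(t_i)
    mean_relative_phase_ : (n,) ndarray — phi_bar_k (nan = undefined)
    rho_k_ : (n,) ndarray — individual synchrony in [0, 1]
    rho_group_t_ : (N,) ndarray — continuous group synchrony
    rho_group_ : float — trial-level group synchrony
    degenerate_mask_ : (N,) ndarray of bool
    result_ : ClusterPhaseResult
    """

    def __init__(
        self,
        degenerate_policy: str = "exclude",
        undefined_phi_bar: str = "zero",
        from_displacement: bool = False,
        phase_method: str = "hilbert",
        preprocess_config=None,
        sample_rate: float | None = None,
    ):
        self.degenerate_policy = degenerate_policy
        self.undefined_phi_bar = undefined_phi_bar
        self.from_displacement = from_displacement
        self.phase_method = phase_method
        self.preprocess_config = preprocess_config
        self.sample_rate = sample_rate

    def fit(self, X, y=None):
        if isinstance(X, MovementTimeSeries) or self.from_displacement:
            series = X
            if not isinstance(series, MovementTimeSeries):
                if self.sample_rate is None:
                    raise ValidationError("sample_rate must be set to analyze a plain array")
                series = MovementTimeSeries(np.asarray(X, dtype=float).T, sample_rate=self.sample_rate)
            result = analyze_trial(
                series,
                preprocess_config=self.preprocess_config,
                phase_method=self.phase_method,
                degenerate_policy=self.degenerate_policy,
                undefined_phi_bar=self.undefined_phi_bar,
            )
        else:
            theta = X
            if not isinstance(theta, PhaseTimeSeries):
                arr = wrap_angle(np.asarray(X, dtype=float).T)
                theta = PhaseTimeSeries(arr, sample_rate=self.sample_rate or 1.0, method_tag="synthetic")
            result = _compute_result(
                theta,
                degenerate_policy=self.degenerate_policy,
                undefined_phi_bar=self.undefined_phi_bar,
            )
        self.result_ = result
        self.cluster_phase_ = result.q
        self.relative_phase_ = result.phi
        self.mean_relative_phase_ = result.phi_bar
        self.rho_k_ = result.rho_k
        self.rho_group_t_ = result.rho_group_t
        self.rho_group_ = result.rho_group
        self.degenerate_mask_ = result.degenerate_mask
        return self

    def score(self, X=None, y=None) -> float:
        """Trial-level group synchrony rho_group of the fitted trial."""
        if not hasattr(self, "rho_group_"):
            raise ValidationError("ClusterPhaseAnalyzer has not been fitted")
        return self.rho_group_
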