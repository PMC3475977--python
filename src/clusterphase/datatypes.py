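"""Domain containers for multivariate movement synchrony analysis.

The containers are thin, validated wrappers around NumPy arrays with the
bookkeeping (sampling rate, participant labels) that a trial of group
movement data carries around.  Row orientation is participants x samples,
matching the way per-participant displacement channels are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


class ValidationError(ValueError):
    """Raised when an input fails structural validation (exit code 2 in the CLI)."""


class DegeneracyError(RuntimeError):
    """Raised when a statistic is mathematically undefined for the given data."""


def _validate_matrix(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValidationError(f"{what} must be a 2-D (participants x samples) array, got ndim={arr.ndim}")
    if arr.shape[1] < 2:
        raise ValidationError(f"{what} needs at least 2 samples per row, got {arr.shape[1]}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"{what} contains a non-finite value at row {bad[0]}, sample {bad[1]}; "
            "missing data must be rejected or imputed explicitly"
        )
    return arr


def _default_labels(n: int) -> tuple:
    return tuple(f"p{k + 1}" for k in range(n))


@dataclass(frozen=True)
class MovementTimeSeries:
    """One displacement channel per participant, equal length, common rate.

    Attributes
    ----------
    values : (n, N) ndarray
        Displacement of participant *k* at sample *i*, arbitrary length units.
    sample_rate : float
        Sampling rate in Hz, strictly positive.
    labels : tuple of str
        One identifier per participant.
    time_origin : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sample_rate: float
    labels: tuple = ()
    time_origin: float = 0.0

    def __post_init__(self):
        arr = _validate_matrix(self.values, "MovementTimeSeries.values")
        object.__setattr__(self, "values", arr)
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise ValidationError(f"sample_rate must be positive and finite, got {self.sample_rate}")
        labels = tuple(self.labels) if self.labels else _default_labels(arr.shape[0])
        if len(labels) != arr.shape[0]:
            raise ValidationError(f"{len(labels)} labels for {arr.shape[0]} participants")
        object.__setattr__(self, "labels", labels)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (N / sample_rate)."""
        return self.n_samples / self.sample_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.time_origin + np.arange(self.n_samples) / self.sample_rate

    def with_values(self, values, sample_rate=None) -> "MovementTimeSeries":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
        )


@dataclass(frozen=True)
class PhaseTimeSeries:
    """Instantaneous phases theta_k(t_i) in radians, wrapped to (-pi, pi].

    ``method_tag`` records how the phases were obtained (``hilbert`` or
    ``peak_interpolated``).  ``extrapolated_mask`` flags samples outside the
    first/last detected peak for the peak-interpolation method; they are
    included in statistics by default.
    """

    phases: np.ndarray
    sample_rate: float
    method_tag: str = "hilbert"
    labels: tuple = ()
    extrapolated_mask: np.ndarray | None = None

    _VALID_TAGS = ("hilbert", "peak_interpolated", "synthetic")

    def __post_init__(self):
        arr = _validate_matrix(self.phases, "PhaseTimeSeries.phases")
        if np.any(arr > np.pi + 1e-12) or np.any(arr <= -np.pi - 1e-12):
            raise ValidationError("phases must be wrapped to (-pi, pi]")
        object.__setattr__(self, "phases", arr)
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise ValidationError(f"sample_rate must be positive and finite, got {self.sample_rate}")
        if self.method_tag not in self._VALID_TAGS:
            raise ValidationError(f"method_tag must be one of {self._VALID_TAGS}, got {self.method_tag!r}")
        labels = tuple(self.labels) if self.labels else _default_labels(arr.shape[0])
        if len(labels) != arr.shape[0]:
            raise ValidationError(f"{len(labels)} labels for {arr.shape[0]} participants")
        object.__setattr__(self, "labels", labels)

    @property
    def n_participants(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]


@dataclass(frozen=True)
class ClusterPhaseResult:
    """All per-trial cluster-phase statistics.

    Fields follow the five-step procedure: the cluster phase ``q(t_i)``
    (argument of the mean unit vector across participants), relative phases
    ``phi_k = theta_k - q``, their circular means ``phi_bar`` and resultant
    lengths ``rho_k`` (individual synchrony), the continuous group synchrony
    ``rho_group_t`` and its time average ``rho_group``.
    """

    q: np.ndarray                 # (N,) cluster phase, radians
    phi: np.ndarray               # (n, N) relative phases, radians
    phi_bar: np.ndarray           # (n,) mean relative phase, radians (nan = undefined)
    rho_k: np.ndarray             # (n,) individual synchrony in [0, 1]
    rho_group_t: np.ndarray       # (N,) continuous group synchrony in [0, 1]
    rho_group: float              # trial-level group synchrony in [0, 1]
    degenerate_mask: np.ndarray   # (N,) True where the cluster resultant ~ 0
    sample_rate: float = 1.0
    labels: tuple = ()
    mean_frequency_hz: float | None = None

    @property
    def n_participants(self) -> int:
        return self.phi.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phi.shape[1]

    def sd_phi(self, kind: str = "circular") -> np.ndarray:
        """Relative-phase dispersion per participant, in radians.

        ``circular`` (default): ``sqrt(-2 ln rho_k)``.  ``linear``:
        arithmetic SD of the relative phase after centring it on
        ``phi_bar`` (wrapped deviations).
        """
        from .circular import circular_sd

        if kind == "circular":
            return np.array([circular_sd(r) for r in self.rho_k])
        if kind == "linear":
            from .circular import wrap_angle

            dev = wrap_angle(self.phi - np.where(np.isnan(self.phi_bar), 0.0, self.phi_bar)[:, None])
            return dev.std(axis=1)
        raise ValueError(f"kind must be 'circular' or 'linear', got {kind!r}")


@dataclass(frozen=True)
class DyadicSynchronyMatrix:
    """Pairwise synchrony rho_d and mean dyadic relative phase for all pairs.

    ``rho_d`` is symmetric with unit diagonal; ``phi_bar_d`` is antisymmetric
    (mod 2*pi) off the diagonal, ``phi_bar_d[a, b]`` being the circular mean
    of ``theta_a - theta_b``.
    """

    rho_d: np.ndarray
    phi_bar_d: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        rho = np.asarray(self.rho_d, dtype=float)
        phi = np.asarray(self.phi_bar_d, dtype=float)
        if rho.shape != phi.shape or rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
            raise ValidationError("rho_d and phi_bar_d must be square matrices of equal shape")
        object.__setattr__(self, "rho_d", rho)
        object.__setattr__(self, "phi_bar_d", phi)
        labels = tuple(self.labels) if self.labels else _default_labels(rho.shape[0])
        if len(labels) != rho.shape[0]:
            raise ValidationError(f"{len(labels)} labels for {rho.shape[0]} participants")
        object.__setattr__(self, "labels", labels)

    @property
    def n_participants(self) -> int:
        return self.rho_d.shape[0]

    def pair(self, a: int, b: int) -> tuple:
        """(rho_d, phi_bar_d) for the ordered pair (a, b)."""
        return float(self.rho_d[a, b]), float(self.phi_bar_d[a, b])
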