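"""Instantaneous-phase extraction from conditioned displacement signals.

Two standard estimators for narrowband oscillatory movement:

* ``hilbert`` — argument of the analytic signal (default).  Rows are
  extended by a few mean periods at each end with a sinusoid fitted to the
  edge (a harmonic continuation) before the transform, which suppresses the
  edge distortion a finite-length Hilbert transform produces; the extension
  is discarded afterwards.
* ``peak_interpolated`` — frequency-normalised continuous phase: the phase
  advances by exactly 2*pi between consecutive displacement maxima and is
  linearly interpolated in between (linearly extrapolated, and flagged,
  before the first and after the last peak).

Both are amplitude-scale invariant, which is what makes the downstream
synchrony statistics insensitive to how far each participant moves.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .circular import wrap_angle
from .datatypes import MovementTimeSeries, PhaseTimeSeries, ValidationError

__all__ = ["hilbert_phase", "peak_interpolated_phase", "extract_phase", "PhaseExtractor"]

logger = logging.getLogger(__name__)


def _mean_period_samples(row: np.ndarray, sample_rate: float) -> int:
    """Dominant period of one row in samples (peak-based, FFT fallback)."""
    from .datatypes import DegeneracyError
    from .preprocess import estimate_frequency_peaks

    try:
        f = estimate_frequency_peaks(row, sample_rate)
    except DegeneracyError:
        spectrum = np.abs(np.fft.rfft(row - row.mean()))
        freqs = np.fft.rfftfreq(row.size, d=1.0 / sample_rate)
        k = int(np.argmax(spectrum[1:]) + 1)
        f = freqs[k] if spectrum[k] > 0 else 0.0
    if f <= 0:
        return row.size
    return max(2, min(int(round(sample_rate / f)), row.size - 1))


def _harmonic_extension(row: np.ndarray, pad: int, period: int) -> np.ndarray:
    """Extend a row by ``pad`` samples per end with edge-fitted sinusoids.

    A mirror reflection is not a harmonic continuation (it leaves a slope
    kink at the splice whose ripple corrupts the analytic-signal phase for
    a couple of cycles), so instead each end's last two periods are fitted
    with ``a + b cos(w i) + c sin(w i)`` at the row's dominant frequency and
    the fit is extrapolated outward.
    """
    w = 2.0 * np.pi / period
    m = min(row.size, max(8, 2 * period))
    i = np.arange(row.size, dtype=float)

    def fit(idx, seg):
        design = np.column_stack([np.ones_like(idx), np.cos(w * idx), np.sin(w * idx)])
        coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
        return coef

    def evaluate(coef, idx):
        return coef[0] + coef[1] * np.cos(w * idx) + coef[2] * np.sin(w * idx)

    left = evaluate(fit(i[:m], row[:m]), np.arange(-pad, 0, dtype=float))
    right = evaluate(fit(i[-m:], row[-m:]), i[-1] + np.arange(1, pad + 1, dtype=float))
    return np.concatenate([left, row, right])


def hilbert_phase(series: MovementTimeSeries) -> PhaseTimeSeries:
    """Phase time-series via the analytic signal, wrapped to (-pi, pi].

    Rows should be centred; a row whose mean exceeds 5% of its RMS triggers
    a warning (a DC offset biases the analytic-signal argument).  All-zero
    rows are rejected.  Each row is harmonically extended by three mean
    periods per end before the transform (see :func:`_harmonic_extension`)
    and the extension is discarded afterwards.
    """
    phases = np.empty_like(series.values)
    for k, row in enumerate(series.values):
        rms = np.sqrt(np.mean(row**2))
        if rms == 0:
            raise ValidationError(f"row {k} ({series.labels[k]}) is all zero; phase undefined")
        if abs(row.mean()) > 0.05 * rms:
            logger.warning(
                "row %d (%s) is not centred (|mean| = %.3g > 5%% of RMS %.3g); "
                "Hilbert phase may be biased",
                k, series.labels[k], abs(row.mean()), rms,
            )
        period = _mean_period_samples(row, series.sample_rate)
        pad = min(3 * period, row.size - 1)
        padded = _harmonic_extension(row, pad, period)
        analytic = sps.hilbert(padded)
        phases[k] = np.angle(analytic[pad:pad + row.size])
    return PhaseTimeSeries(
        phases=wrap_angle(phases),
        sample_rate=series.sample_rate,
        method_tag="hilbert",
        labels=series.labels,
    )


def peak_interpolated_phase(
    series: MovementTimeSeries,
    expected_max_hz: float = 2.0,
) -> PhaseTimeSeries:
    """Frequency-normalised phase: +2*pi per inter-peak interval.

    Raises
    ------
    ValidationError
        If any row has fewer than two detected peaks (names the row).
    """
    n, N = series.values.shape
    phases = np.empty((n, N))
    extrapolated = np.zeros((n, N), dtype=bool)
    min_sep = max(1, int(round(0.25 / expected_max_hz * series.sample_rate)))
    idx = np.arange(N, dtype=float)
    for k, row in enumerate(series.values):
        prominence = 0.1 * np.ptp(row) if np.ptp(row) > 0 else None
        peaks, _ = sps.find_peaks(row, distance=min_sep, plateau_size=1, prominence=prominence)
        if len(peaks) < 2:
            raise ValidationError(
                f"row {k} ({series.labels[k]}) has {len(peaks)} peak(s); "
                "peak-interpolated phase needs at least 2"
            )
        # unwrapped phase: 2*pi*j at peak j, linear in between and beyond
        peak_phase = 2.0 * np.pi * np.arange(len(peaks), dtype=float)
        unwrapped = np.interp(idx, peaks.astype(float), peak_phase)
        first_slope = 2.0 * np.pi / (peaks[1] - peaks[0])
        last_slope = 2.0 * np.pi / (peaks[-1] - peaks[-2])
        before, after = idx < peaks[0], idx > peaks[-1]
        unwrapped[before] = peak_phase[0] - first_slope * (peaks[0] - idx[before])
        unwrapped[after] = peak_phase[-1] + last_slope * (idx[after] - peaks[-1])
        extrapolated[k] = before | after
        phases[k] = wrap_angle(unwrapped)
    return PhaseTimeSeries(
        phases=phases,
        sample_rate=series.sample_rate,
        method_tag="peak_interpolated",
        labels=series.labels,
        extrapolated_mask=extrapolated,
    )


def extract_phase(series: MovementTimeSeries, method: str = "hilbert") -> PhaseTimeSeries:
    """Dispatch to :func:`hilbert_phase` or :func:`peak_interpolated_phase`."""
    if method == "hilbert":
        return hilbert_phase(series)
    if method == "peak_interpolated":
        return peak_interpolated_phase(series)
    raise ValidationError(f"unknown phase method {method!r}; use 'hilbert' or 'peak_interpolated'")


class PhaseExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping displacement to instantaneous phase.

    Accepts a :class:`MovementTimeSeries` (returns a
    :class:`PhaseTimeSeries`) or a plain ``(n_samples, n_participants)``
    array with ``sample_rate`` set (returns an array of the same shape).
    """

    def __init__(self, method: str = "hilbert", sample_rate: float | None = None):
        self.method = method
        self.sample_rate = sample_rate

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if isinstance(X, MovementTimeSeries):
            return extract_phase(X, self.method)
        if self.sample_rate is None:
            raise ValidationError("sample_rate must be set to transform a plain array")
        series = MovementTimeSeries(np.asarray(X, dtype=float).T, sample_rate=self.sample_rate)
        return extract_phase(series, self.method).phases.T
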