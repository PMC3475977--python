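"""Surrogate-data chance baselines for the synchrony statistics.

A surrogate trial preserves each participant's own signal structure while
destroying any genuine between-participant coupling; the synchrony of many
surrogates forms an empirical null distribution against which an observed
``rho_group`` can be tested without a behavioural control condition.

Three standard constructions are provided:

* ``time_shift`` (default, most conservative for oscillatory data) — each
  row is circularly rotated by an independent random offset of at least one
  mean period, preserving the row exactly.
* ``phase_randomize`` — each row's Fourier phases are randomised
  independently, preserving the row's amplitude spectrum.
* ``row_shuffle`` — participant rows are re-paired across several recorded
  trials, preserving rows exactly but destroying within-trial pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import MovementTimeSeries, ValidationError

__all__ = ["SurrogateConfig", "make_surrogate", "chance_level", "ChanceLevelResult", "SurrogateTest"]


@dataclass(frozen=True)
class SurrogateConfig:
    """Null-distribution parameters.

    quantiles are upper tail probabilities of interest (e.g. 0.95, 0.99);
    the empirical p-value uses the add-one rule, so the smallest reportable
    p is ``1 / (n_surrogates + 1)``.
    """

    method: str = "time_shift"
    n_surrogates: int = 200
    seed: int = 0
    quantiles: tuple = (0.95, 0.99)

    def __post_init__(self):
        if self.method not in ("time_shift", "phase_randomize", "row_shuffle"):
            raise ValidationError(
                f"method must be 'time_shift', 'phase_randomize' or 'row_shuffle', got {self.method!r}"
            )
        if self.n_surrogates < 1:
            raise ValidationError(f"n_surrogates must be >= 1, got {self.n_surrogates}")
        if any(not 0 < q < 1 for q in self.quantiles):
            raise ValidationError(f"quantiles must lie in (0, 1), got {self.quantiles}")


def _mean_period_samples(series: MovementTimeSeries) -> int:
    from .phase import _mean_period_samples as row_period

    periods = [row_period(row, series.sample_rate) for row in series.values]
    return int(round(np.mean(periods)))


def make_surrogate(
    x: MovementTimeSeries,
    method: str = "time_shift",
    seed: int = 0,
    trials=None,
) -> MovementTimeSeries:
    """One surrogate copy of ``x`` with between-row coupling destroyed.

    ``row_shuffle`` requires ``trials``: a sequence of at least two
    recordings (including or excluding ``x``) of the same participants;
    each output row is drawn from a randomly chosen trial.
    """
    rng = np.random.default_rng(seed)
    n, N = x.values.shape
    if method == "time_shift":
        period = _mean_period_samples(x)
        if N < 2 * period:
            raise ValidationError(
                f"time_shift needs at least 2 mean periods ({2 * period} samples), got {N}"
            )
        out = np.empty_like(x.values)
        for k in range(n):
            shift = int(rng.integers(period, N - period + 1))
            out[k] = np.roll(x.values[k], shift)
        return x.with_values(out)
    if method == "phase_randomize":
        out = np.empty_like(x.values)
        for k in range(n):
            spectrum = np.fft.rfft(x.values[k])
            phases = rng.uniform(0.0, 2.0 * np.pi, size=spectrum.size)
            phases[0] = 0.0  # keep DC real
            if N % 2 == 0:
                phases[-1] = 0.0  # keep Nyquist real
            out[k] = np.fft.irfft(np.abs(spectrum) * np.exp(1j * phases), n=N)
        return x.with_values(out)
    if method == "row_shuffle":
        if trials is None or len(trials) < 2:
            raise ValidationError("row_shuffle needs at least two trials to re-pair rows across")
        for t in trials:
            if t.values.shape != (n, N):
                raise ValidationError("row_shuffle trials must all have the same shape")
        picks = rng.integers(0, len(trials), size=n)
        out = np.vstack([trials[picks[k]].values[k] for k in range(n)])
        return x.with_values(out)
    raise ValidationError(f"unknown surrogate method {method!r}")


@dataclass(frozen=True)
class ChanceLevelResult:
    """Null distribution of rho_group plus the observed value and p."""

    observed: float
    null: np.ndarray          # sorted ascending
    quantiles: dict           # probability -> null quantile
    p_value: float
    method: str
    n_surrogates: int

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())


def chance_level(
    x: MovementTimeSeries,
    config: SurrogateConfig | None = None,
    trials=None,
    **analysis_options,
) -> ChanceLevelResult:
    """Empirical chance level of rho_group for one recorded trial.

    Runs the full cluster-phase analysis on ``config.n_surrogates``
    surrogate copies of ``x`` and on ``x`` itself, with identical analysis
    options.  The empirical p uses the add-one rule
    ``p = (1 + #{null >= observed}) / (1 + n_surrogates)``.

    Per-surrogate seeds are spawned deterministically from ``config.seed``,
    so a run is exactly reproducible.
    """
    from .cluster import analyze_trial

    cfg = config or SurrogateConfig()
    if cfg.n_surrogates < 20 and cfg.quantiles:
        raise ValidationError("n_surrogates must be >= 20 for quantile reporting")
    observed = analyze_trial(x, **analysis_options).rho_group
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_surrogates)
    null = np.empty(cfg.n_surrogates)
    for j in range(cfg.n_surrogates):
        surr = make_surrogate(x, method=cfg.method, seed=int(child_seeds[j]), trials=trials)
        null[j] = analyze_trial(surr, **analysis_options).rho_group
    null.sort()
    quantiles = {q: float(np.quantile(null, q)) for q in cfg.quantiles}
    p = (1 + int(np.sum(null >= observed))) / (1 + cfg.n_surrogates)
    return ChanceLevelResult(
        observed=observed,
        null=null,
        quantiles=quantiles,
        p_value=p,
        method=cfg.method,
        n_surrogates=cfg.n_surrogates,
    )


class SurrogateTest(BaseEstimator):
    """Estimator form of the surrogate chance-level test.

    ``fit(X)`` with a :class:`MovementTimeSeries` computes the observed
    rho_group, the surrogate null distribution, its quantiles and the
    empirical p-value.

    Attributes (after ``fit``)
    --------------------------
    observed_ : float
    null_ : (n_surrogates,) ndarray, sorted
    quantiles_ : dict
    p_value_ : float
    """

    def __init__(
        self,
        method: str = "time_shift",
        n_surrogates: int = 200,
        seed: int = 0,
        quantiles: tuple = (0.95, 0.99),
        phase_method: str = "hilbert",
        preprocess_config=None,
    ):
        self.method = method
        self.n_surrogates = n_surrogates
        self.seed = seed
        self.quantiles = quantiles
        self.phase_method = phase_method
        self.preprocess_config = preprocess_config

    def fit(self, X, y=None, trials=None):
        cfg = SurrogateConfig(
            method=self.method,
            n_surrogates=self.n_surrogates,
            seed=self.seed,
            quantiles=tuple(self.quantiles),
        )
        res = chance_level(
            X,
            cfg,
            trials=trials,
            phase_method=self.phase_method,
            preprocess_config=self.preprocess_config,
        )
        self.result_ = res
        self.observed_ = res.observed
        self.null_ = res.null
        self.quantiles_ = res.quantiles
        self.p_value_ = res.p_value
        return self
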