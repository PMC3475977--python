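"""CSV input/output and per-trial report writers.

Interchange format: plain CSV with one column per participant, an optional
leading time column, and a comment header line ``# sample_rate_hz=<rate>``
carrying the sampling rate.  Reports mirror the tabular layout practitioners
expect for this analysis: a per-participant table (mean relative phase and
its dispersion in degrees, rho_k), a group summary, the continuous
rho_group_t series, and the upper-triangular dyadic matrix.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClusterPhaseResult,
    DyadicSynchronyMatrix,
    MovementTimeSeries,
    ValidationError,
)

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_reports",
    "individual_table",
    "dyadic_table",
]

_TIME_COLUMNS = ("time", "time_s", "t", "seconds")
_FMT = "%.6g"


def read_timeseries_csv(path, sample_rate: float | None = None) -> MovementTimeSeries:
    """Read a delimited trial file into a :class:`MovementTimeSeries`.

    The sampling rate is taken from (in order of precedence) the
    ``sample_rate`` argument, a ``# sample_rate_hz=<value>`` header line, or
    a time column named one of ``time, time_s, t, seconds``.  A time column
    must be uniformly spaced to within 0.1%; ragged or non-numeric content
    is rejected with the offending cell named.
    """
    path = Path(path)
    header_rate = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if stripped.startswith("sample_rate_hz"):
                try:
                    header_rate = float(stripped.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise ValidationError(f"malformed sample_rate_hz header in {path}: {line!r}") from exc
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc

    time_col = next((c for c in df.columns if c.strip().lower() in _TIME_COLUMNS), None)
    time_origin = 0.0
    if time_col is not None:
        t = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
        if np.any(~np.isfinite(t)):
            bad = int(np.argwhere(~np.isfinite(t))[0][0])
            raise ValidationError(f"non-numeric time value at row {bad}, column {time_col!r} in {path}")
        dt = np.diff(t)
        if dt.size and (dt.min() <= 0 or (dt.max() - dt.min()) > 1e-3 * dt.mean()):
            raise ValidationError(
                f"time column {time_col!r} in {path} is not uniformly spaced (jitter > 0.1%)"
            )
        inferred = 1.0 / dt.mean() if dt.size else None
        time_origin = float(t[0])
        df = df.drop(columns=[time_col])
    else:
        inferred = None

    rate = sample_rate if sample_rate is not None else (header_rate if header_rate is not None else inferred)
    if rate is None:
        raise ValidationError(
            f"no sampling rate for {path}: pass sample_rate=, add a '# sample_rate_hz=' "
            "header, or include a time column"
        )

    values = np.empty((len(df.columns), len(df)))
    for j, col in enumerate(df.columns):
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            bad = int(np.argwhere(~np.isfinite(v))[0][0])
            raise ValidationError(f"non-finite or non-numeric value at row {bad}, column {col!r} in {path}")
        values[j] = v
    return MovementTimeSeries(
        values=values,
        sample_rate=float(rate),
        labels=tuple(str(c) for c in df.columns),
        time_origin=time_origin,
    )


def write_timeseries_csv(series: MovementTimeSeries, path) -> Path:
    """Write a trial to CSV with the metadata header; lossless round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(series.values.T, columns=list(series.labels))
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={series.sample_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def individual_table(result: ClusterPhaseResult, sd_kind: str = "circular") -> pd.DataFrame:
    """Per-participant table: mean relative phase and dispersion (degrees), rho_k."""
    sd = result.sd_phi(sd_kind)
    return pd.DataFrame(
        {
            "participant": list(result.labels),
            "phi_bar_deg": np.degrees(result.phi_bar),
            "sd_phi_deg": np.degrees(sd),
            "rho_k": result.rho_k,
        }
    )


def dyadic_table(dyads: DyadicSynchronyMatrix) -> pd.DataFrame:
    """Upper-triangle pair list: participant_a, participant_b, rho_d, phi_bar_d_deg."""
    rows = []
    n = dyads.n_participants
    for a in range(n):
        for b in range(a + 1, n):
            rho_d, phi_bar_d = dyads.pair(a, b)
            rows.append(
                {
                    "participant_a": dyads.labels[a],
                    "participant_b": dyads.labels[b],
                    "rho_d": rho_d,
                    "phi_bar_d_deg": np.degrees(phi_bar_d),
                }
            )
    return pd.DataFrame(rows)


def write_reports(
    result: ClusterPhaseResult,
    dyads: DyadicSynchronyMatrix | None = None,
    null=None,
    outdir="reports",
    manifest_extra: dict | None = None,
) -> dict:
    """Write the per-trial report files; returns {name: path}.

    Files: ``individual.csv`` (phi_bar/SD in degrees, rho_k),
    ``group_summary.csv`` (rho_group plus null quantiles and p when a
    surrogate result is given), ``rho_group_t.csv`` (time_s, rho_group_t in
    radians-free units), ``dyadic.csv`` (upper-triangle pairs), and
    ``manifest.json`` recording versions and any configuration passed in
    ``manifest_extra`` so a run can be reproduced bit-exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ind = individual_table(result)
    ind.to_csv(outdir / "individual.csv", index=False, float_format=_FMT)
    paths["individual"] = outdir / "individual.csv"

    summary = {"rho_group": [result.rho_group]}
    if result.mean_frequency_hz is not None:
        summary["mean_frequency_hz"] = [result.mean_frequency_hz]
    summary["n_degenerate_steps"] = [int(result.degenerate_mask.sum())]
    if null is not None:
        summary["null_mean"] = [null.null_mean]
        for q, v in null.quantiles.items():
            summary[f"null_q{int(round(q * 100))}"] = [v]
        summary["p_value"] = [null.p_value]
        summary["surrogate_method"] = [null.method]
        summary["n_surrogates"] = [null.n_surrogates]
    pd.DataFrame(summary).to_csv(outdir / "group_summary.csv", index=False, float_format=_FMT)
    paths["group_summary"] = outdir / "group_summary.csv"

    t = np.arange(result.n_samples) / result.sample_rate
    pd.DataFrame({"time_s": t, "rho_group_t": result.rho_group_t}).to_csv(
        outdir / "rho_group_t.csv", index=False, float_format=_FMT
    )
    paths["rho_group_t"] = outdir / "rho_group_t.csv"

    if dyads is not None:
        dyadic_table(dyads).to_csv(outdir / "dyadic.csv", index=False, float_format=_FMT)
        paths["dyadic"] = outdir / "dyadic.csv"

    if null is not None:
        pd.DataFrame({"rho_group_null": null.null}).to_csv(
            outdir / "null_distribution.csv", index=False, float_format=_FMT
        )
        paths["null_distribution"] = outdir / "null_distribution.csv"

    manifest = {
        "package": "clusterphase",
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_participants": result.n_participants,
        "n_samples": result.n_samples,
        "sample_rate": result.sample_rate,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest"] = outdir / "manifest.json"
    return paths
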