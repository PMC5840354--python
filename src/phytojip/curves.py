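"""Kinetic curve containers and delimited-text I/O.

Fast fluorimeters record fluorescence (and 820 nm transmittance) on a
log-spaced time grid from ~10 us to ~1 s.  Curves are stored as plain
arrays of seconds and instrument units; all downstream interpolation is
linear in signal versus log10(time), which respects the log-spaced
sampling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_TIME_FACTORS = {
    "s": 1.0,
    "seconds": 1.0,
    "ms": 1e-3,
    "milliseconds": 1e-3,
    "us": 1e-6,
    "microseconds": 1e-6,
}

#: Minimum number of samples for a usable fast transient.
MIN_SAMPLES = 20
#: Minimum time span, in decades, for a usable fast transient.
MIN_DECADES = 4.0


class CurveValidationError(ValueError):
    """Raised when a kinetic record violates a structural invariant."""


class CurveParseError(ValueError):
    """Raised when a delimited transient file cannot be parsed."""


def _validate_arrays(times: np.ndarray, values: np.ndarray) -> None:
    if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
        raise CurveValidationError(
            "times and values must be 1-D arrays of equal length"
        )
    if times.size < MIN_SAMPLES:
        raise CurveValidationError(
            f"curve has {times.size} samples; at least {MIN_SAMPLES} required"
        )
    if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
        raise CurveValidationError("times and values must be finite")
    if np.any(times <= 0):
        raise CurveValidationError("times must be strictly positive seconds")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        bad = times[1:][diffs <= 0][0]
        raise CurveValidationError(
            f"times must be strictly increasing; violation at t={bad!r} s"
        )
    if np.any(values <= 0):
        raise CurveValidationError("signal values must be strictly positive")
    decades = np.log10(times[-1] / times[0])
    if decades < MIN_DECADES:
        raise CurveValidationError(
            f"time range spans {decades:.2f} decades; "
            f">= {MIN_DECADES:g} required"
        )


@dataclass(frozen=True)
class InductionCurve:
    """A sampled fluorescence induction transient.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, spanning at least
        four decades with at least 20 points.
    values
        Fluorescence in instrument units, strictly positive.
    label
        Free-text sample identifier.
    metadata
        Genotype/treatment tags carried through analysis.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        _validate_arrays(t, v)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.times.size

    def interpolate(self, t: float | np.ndarray) -> np.ndarray:
        """Signal at time(s) *t* by linear interpolation in log10(time)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise CurveValidationError(
                f"time outside sampled range "
                f"[{self.times[0]:g}, {self.times[-1]:g}] s"
            )
        return np.interp(np.log10(t), np.log10(self.times), self.values)

    def scaled(self, factor: float) -> "InductionCurve":
        return InductionCurve(
            self.times, self.values * factor, self.label, dict(self.metadata)
        )


def _read_two_column(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a two-column delimited table, sniffing comma vs tab."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#", skip_blank_lines=True, dtype=str)
    except Exception as exc:  # malformed structure
        raise CurveParseError(f"cannot parse transient file: {exc}") from exc
    if df.shape[1] < 2:
        raise CurveParseError(
            f"expected two columns (time, signal); found {df.shape[1]}"
        )
    df = df.iloc[:, :2]
    # optional single header line
    first = df.iloc[0]
    try:
        [float(x) for x in first]
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def read_transient(
    path: str | Path | io.TextIOBase,
    time_unit: str = "s",
    label: str | None = None,
    metadata: dict | None = None,
) -> InductionCurve:
    """Read a two-column (time, fluorescence) delimited file.

    Parameters
    ----------
    path
        CSV or TSV file; an optional one-line header is skipped.
    time_unit
        Unit of the time column: ``"s"``, ``"ms"`` or ``"us"``
        (long forms accepted).  Times are converted to seconds.

    Returns
    -------
    InductionCurve
        Validated curve with rows sorted by time.

    Raises
    ------
    CurveParseError
        Non-numeric cell (the offending row is named) or malformed table.
    CurveValidationError
        Duplicate times, fewer than 20 rows, or other invariant violation.
    """
    if time_unit not in _TIME_FACTORS:
        raise ValueError(f"unknown time unit {time_unit!r}")
    df = _read_two_column(path)
    times = np.empty(len(df))
    values = np.empty(len(df))
    for i, (traw, vraw) in enumerate(zip(df.iloc[:, 0], df.iloc[:, 1])):
        try:
            times[i] = float(traw)
            values[i] = float(vraw)
        except (TypeError, ValueError):
            raise CurveParseError(
                f"non-numeric cell in data row {i + 1}: "
                f"({traw!r}, {vraw!r})"
            ) from None
    times = times * _TIME_FACTORS[time_unit]
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        raise CurveValidationError(
            f"duplicated time value {times[dup[0]]:g} s"
        )
    name = label if label is not None else (
        Path(path).stem if isinstance(path, (str, Path)) else ""
    )
    return InductionCurve(times, values, name, metadata or {})


def write_transient(
    curve: "InductionCurve",
    path: str | Path | io.TextIOBase,
    time_unit: str = "s",
) -> None:
    """Write a curve as a two-column CSV (header ``time,signal``)."""
    factor = _TIME_FACTORS[time_unit]
    df = pd.DataFrame(
        {"time": curve.times / factor, "signal": curve.values}
    )
    df.to_csv(path, index=False, float_format="%.12g")
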