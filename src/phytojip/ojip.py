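"""JIP-test analysis of fast chlorophyll *a* fluorescence (OJIP) transients.

The OJIP transient is the polyphasic fluorescence rise of a dark-adapted
leaf under saturating light, with inflections O (origin, minimal
fluorescence Fo), J (~2 ms), I (~30 ms) and the peak P (maximal
fluorescence Fm).  The JIP-test reduces a transient to a handful of
biophysically interpretable parameters:

* ``Fv/Fm = (Fm - Fo)/Fm`` — maximum quantum yield of PSII photochemistry;
* ``V_t = (F_t - Fo)/(Fm - Fo)`` — relative variable fluorescence, with
  ``V_J`` and ``V_I`` its values at the J and I steps;
* ``M0 = 4 (F300 - Fo)/(Fm - Fo)`` per ms — initial slope of the V rise,
  proportional to the net rate of Q_A reduction;
* ``RC/ABS = (1 - Fo/Fm) / [4 (F300 - Fo)/(F_J - Fo)]`` — density of
  active PSII reaction centers per absorbed photon flux;
* ``PI(abs) = RC/ABS * [(Fv/Fm)/(1 - Fv/Fm)] * [(Fm - F_J)/(F_J - Fo)]``
  — the performance index combining reaction-center density, trapping
  yield and electron transfer past Q_A;
* the area between the Fm level and the transient (a plastoquinone-pool
  size proxy), raw or normalized by Fv (the Sm convention).

Fiducial values are read at fixed marker times (Fo at 20 us, F300 at
300 us, F_J at 2 ms, F_I at 30 ms by default) by linear interpolation of
fluorescence against log10(time); Fm is the global maximum of the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from phytojip.curves import CurveValidationError, InductionCurve


class DegenerateTransientError(ValueError):
    """Raised for transients with no variable fluorescence (Fm <= Fo)."""


class UndefinedRatioError(ZeroDivisionError, ValueError):
    """Raised when a JIP ratio's denominator collapses (e.g. F300 <= Fo)."""


@dataclass(frozen=True)
class MarkerConfig:
    """Times (seconds) at which the fiducial fluorescence values are read.

    Defaults follow common fast-fluorimeter convention: Fo at the first
    reliable sample (20 us), F300 at 300 us, F_J at 2 ms, F_I at 30 ms.
    """

    t_fo: float = 20e-6
    t_f300: float = 300e-6
    t_fj: float = 2e-3
    t_fi: float = 30e-3


DEFAULT_MARKERS = MarkerConfig()


@dataclass(frozen=True)
class OJIPMarkers:
    """The five fiducial fluorescence values of an OJIP transient.

    ``flags`` records physical-plausibility violations (e.g. a
    non-monotone O-J rise) without failing extraction.
    """

    fo: float
    f300: float
    fj: float
    fi: float
    fm: float
    t_fm: float
    t_fo: float = DEFAULT_MARKERS.t_fo
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("fo", "f300", "fj", "fi", "fm"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"marker {name} is not finite")
        if self.fo <= 0:
            raise ValueError("Fo must be positive")
        if self.fm < max(self.fo, self.f300, self.fj, self.fi):
            raise ValueError("Fm must be >= every other marker")

    @property
    def fv(self) -> float:
        """Maximal variable fluorescence Fv = Fm - Fo."""
        return self.fm - self.fo


@dataclass(frozen=True)
class JIPParameters:
    """Derived JIP-test quantities for one transient."""

    fv_fm: float
    v_j: float
    v_i: float
    m0: float  # per ms
    rc_abs: float
    pi_abs: float
    area: float  # fluorescence * s
    sm: float  # s
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class VCurve:
    """Relative variable fluorescence V_t (or double-normalized W_t).

    ``span_tag`` names the normalization span: OP for the full
    Fo-to-Fm span (V_t proper), OJ/OI for double-normalized curves
    anchored at F_J or F_I.
    """

    times: np.ndarray
    v_values: np.ndarray
    span_tag: str = "OP"
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.v_values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and v_values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.span_tag not in ("OJ", "OI", "OP"):
            raise ValueError(f"unknown span tag {self.span_tag!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "v_values", v)


def extract_markers(
    curve: InductionCurve, config: MarkerConfig = DEFAULT_MARKERS
) -> OJIPMarkers:
    """Read Fo, F300, F_J, F_I and Fm from a transient.

    Fo, F300, F_J and F_I are interpolated linearly in fluorescence vs
    log10(time) at the configured marker times; Fm is the global maximum
    of the record with ties broken by the earliest time.

    Raises
    ------
    CurveValidationError
        A marker time falls outside the sampled range.
    DegenerateTransientError
        Fm <= Fo (no variable fluorescence).
    """
    marker_times = (config.t_fo, config.t_f300, config.t_fj, config.t_fi)
    fo, f300, fj, fi = (float(curve.interpolate(t)) for t in marker_times)
    i_max = int(np.argmax(curve.values))  # argmax returns first tie
    fm = float(curve.values[i_max])
    t_fm = float(curve.times[i_max])
    if fm <= fo:
        raise DegenerateTransientError(
            f"degenerate transient {curve.label!r}: Fm={fm:g} <= Fo={fo:g}"
        )
    flags = []
    if not (fo <= f300 <= fj):
        flags.append("non-monotone O-J rise")
    if fj > fi:
        flags.append("J step above I step")
    # interpolated markers can sit epsilon above the sampled maximum
    fm = max(fm, fo, f300, fj, fi)
    return OJIPMarkers(
        fo=fo, f300=f300, fj=fj, fi=fi, fm=fm, t_fm=t_fm,
        t_fo=config.t_fo, flags=tuple(flags),
    )


def fv_fm(markers: OJIPMarkers) -> float:
    """Maximum quantum yield of PSII photochemistry, (Fm - Fo)/Fm."""
    if markers.fm <= 0:
        raise ValueError("Fm must be positive")
    if markers.fo > markers.fm:
        raise ValueError("inconsistent markers: Fo > Fm")
    return (markers.fm - markers.fo) / markers.fm


def initial_slope(
    markers: OJIPMarkers, *, chord_ms: float = 0.25
) -> float:
    """Initial slope M0 = dV/dt0 of the relative variable fluorescence.

    Computed as the chord slope of V over the first ``chord_ms``
    milliseconds: ``M0 = (F300 - Fo)/(Fm - Fo) / chord_ms`` per ms,
    i.e. the conventional ``4 (F300 - Fo)/Fv`` for the 0.25 ms chord
    between the Fo marker and 300 us.
    """
    if markers.fm <= markers.fo:
        raise DegenerateTransientError("Fm must exceed Fo")
    return (markers.f300 - markers.fo) / (markers.fm - markers.fo) / chord_ms


def fitted_initial_slope(
    curve: InductionCurve,
    markers: OJIPMarkers,
    *,
    t_lo: float = 50e-6,
    t_hi: float = 300e-6,
) -> float:
    """Least-squares alternative to the chord M0 (per ms).

    Fits V_t linearly against time over [t_lo, t_hi] (50-300 us by
    default) and returns the slope; useful when the earliest samples are
    noisy.
    """
    if markers.fm <= markers.fo:
        raise DegenerateTransientError("Fm must exceed Fo")
    mask = (curve.times >= t_lo) & (curve.times <= t_hi)
    if mask.sum() < 2:
        raise CurveValidationError(
            f"fewer than 2 samples in [{t_lo:g}, {t_hi:g}] s"
        )
    t_ms = curve.times[mask] * 1e3
    v = (curve.values[mask] - markers.fo) / markers.fv
    slope, _ = np.polyfit(t_ms, v, 1)
    return float(slope)


def rc_abs(markers: OJIPMarkers) -> float:
    """Density of active PSII reaction centers per absorbed photon flux.

    ``RC/ABS = (1 - Fo/Fm) / [4 (F300 - Fo)/(F_J - Fo)]``.
    """
    if markers.f300 <= markers.fo:
        raise UndefinedRatioError("F300 must exceed Fo for RC/ABS")
    if markers.fj <= markers.fo:
        raise UndefinedRatioError("F_J must exceed Fo for RC/ABS")
    specific_slope = 4.0 * (markers.f300 - markers.fo) / (markers.fj - markers.fo)
    return (1.0 - markers.fo / markers.fm) / specific_slope


def pi_abs(markers: OJIPMarkers) -> float:
    """Performance index of PSII activity, PI(abs).

    The product of reaction-center density, the trapping-yield odds
    ratio, and the efficiency of electron transfer past Q_A:
    ``RC/ABS * [(Fv/Fm)/(1 - Fv/Fm)] * [(Fm - F_J)/(F_J - Fo)]``.
    """
    phi = fv_fm(markers)
    if phi >= 1.0:
        raise UndefinedRatioError("Fv/Fm must be < 1 for PI(abs)")
    if markers.fj <= markers.fo:
        raise UndefinedRatioError("F_J must exceed Fo for PI(abs)")
    return (
        rc_abs(markers)
        * (phi / (1.0 - phi))
        * ((markers.fm - markers.fj) / (markers.fj - markers.fo))
    )


def relative_variable_fluorescence(
    curve: InductionCurve, markers: OJIPMarkers
) -> VCurve:
    """Pointwise V_t = (F_t - Fo)/(Fm - Fo) over the full record."""
    if markers.fm <= markers.fo:
        raise DegenerateTransientError("Fm must exceed Fo")
    v = (curve.values - markers.fo) / markers.fv
    return VCurve(curve.times, v, "OP", curve.label, dict(curve.metadata))


_SPAN_ANCHOR = {"OJ": "fj", "OI": "fi", "OP": "fm"}


def double_normalize(
    curve: InductionCurve, markers: OJIPMarkers, span: str = "OP"
) -> VCurve:
    """Double-normalized fluorescence W_t = (F_t - Fo)/(F_anchor - Fo).

    ``span`` selects the upper anchor: OJ -> F_J, OI -> F_I, OP -> Fm
    (in which case W_t is V_t).
    """
    if span not in _SPAN_ANCHOR:
        raise ValueError(f"span must be one of OJ, OI, OP; got {span!r}")
    anchor = getattr(markers, _SPAN_ANCHOR[span])
    if anchor <= markers.fo:
        raise UndefinedRatioError(
            f"{span} anchor ({anchor:g}) must exceed Fo ({markers.fo:g})"
        )
    w = (curve.values - markers.fo) / (anchor - markers.fo)
    return VCurve(curve.times, w, span, curve.label, dict(curve.metadata))


def difference_kinetics(treated: VCurve, control: VCurve) -> VCurve:
    """Difference kinetics dV(t) = V_treated(t) - V_control(t).

    Evaluated on the control's grid over the overlapping time range,
    resampling the treated curve linearly in log10(time).
    """
    if treated.span_tag != control.span_tag:
        raise ValueError(
            f"span mismatch: {treated.span_tag} vs {control.span_tag}"
        )
    lo = max(treated.times[0], control.times[0])
    hi = min(treated.times[-1], control.times[-1])
    if lo >= hi:
        raise ValueError("curves have no overlapping time range")
    mask = (control.times >= lo) & (control.times <= hi)
    t = control.times[mask]
    v_treat = np.interp(np.log10(t), np.log10(treated.times), treated.v_values)
    dv = v_treat - control.v_values[mask]
    return VCurve(
        t, dv, treated.span_tag,
        label=f"{treated.label} - {control.label}",
    )


def area_over_curve(
    curve: InductionCurve,
    markers: OJIPMarkers,
    normalized: bool = False,
) -> float:
    """Area between the Fm level and the transient.

    Trapezoidal integral of ``Fm - F_t`` over linear time from the Fo
    marker time to t_Fm; a proxy for the plastoquinone pool that must be
    reduced to close all PSII centers.  With ``normalized=True`` the
    integral is divided by Fv (the Sm convention, units of seconds).
    """
    if markers.fm <= markers.fo:
        raise DegenerateTransientError("Fm must exceed Fo")
    t0, t1 = markers.t_fo, markers.t_fm
    if t1 <= t0:
        raise CurveValidationError("t_Fm must lie after the Fo marker time")
    inside = (curve.times > t0) & (curve.times < t1)
    t = np.concatenate(([t0], curve.times[inside], [t1]))
    f = np.concatenate(
        ([curve.interpolate(t0)], curve.values[inside], [curve.interpolate(t1)])
    )
    area = float(np.trapezoid(np.maximum(markers.fm - f, 0.0), t))
    return area / markers.fv if normalized else area


def smooth_median3(curve: InductionCurve) -> InductionCurve:
    """Optional 3-point moving-median smoother for noisy transients."""
    v = curve.values
    sm = v.copy()
    stacked = np.stack([v[:-2], v[1:-1], v[2:]])
    sm[1:-1] = np.median(stacked, axis=0)
    return InductionCurve(curve.times, sm, curve.label, dict(curve.metadata))


def average_transients(curves: list[InductionCurve]) -> InductionCurve:
    """Pointwise mean transient on the first curve's grid.

    Other curves are resampled by linear interpolation in log10(time);
    the grid is clipped to the overlapping time range of all inputs.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    lo = max(c.times[0] for c in curves)
    hi = min(c.times[-1] for c in curves)
    if lo >= hi:
        raise ValueError("curves have no overlapping time range")
    ref = curves[0]
    mask = (ref.times >= lo) & (ref.times <= hi)
    t = ref.times[mask]
    stack = np.stack([
        np.interp(np.log10(t), np.log10(c.times), c.values) for c in curves
    ])
    return InductionCurve(
        t, stack.mean(axis=0),
        label=f"mean(n={len(curves)})",
        metadata={"n": len(curves)},
    )


def analyze_transient(
    curve: InductionCurve, config: MarkerConfig = DEFAULT_MARKERS
) -> JIPParameters:
    """All JIP parameters of one transient (markers extracted internally)."""
    markers = extract_markers(curve, config)
    vj = (markers.fj - markers.fo) / markers.fv
    vi = (markers.fi - markers.fo) / markers.fv
    return JIPParameters(
        fv_fm=fv_fm(markers),
        v_j=vj,
        v_i=vi,
        m0=initial_slope(markers),
        rc_abs=rc_abs(markers),
        pi_abs=pi_abs(markers),
        area=area_over_curve(curve, markers),
        sm=area_over_curve(curve, markers, normalized=True),
        flags=markers.flags,
    )


_PARAM_COLS = ["fv_fm", "v_j", "v_i", "m0", "rc_abs", "pi_abs", "area", "sm"]
_MARKER_COLS = ["Fo", "F300", "FJ", "FI", "Fm"]


def jip_summary(
    curves: list[InductionCurve],
    group_by: str | None = None,
    reference: str | None = None,
    config: MarkerConfig = DEFAULT_MARKERS,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-curve JIP parameter table plus optional group statistics.

    Parameters
    ----------
    curves
        Transients to analyze.  Degenerate transients are reported as
        flagged rows (NaN parameters) and excluded from group statistics.
    group_by
        Metadata key to group on.  If None, only the per-curve table is
        returned (second element None).
    reference
        Group label against which percent change of each group mean is
        computed (via :func:`phytojip.phenomics.percent_change`).

    Returns
    -------
    (per_curve, groups)
        ``per_curve`` has one row per input curve with columns
        label, Fo, F300, FJ, FI, Fm, fv_fm, v_j, v_i, m0, rc_abs,
        pi_abs, area, sm, flags.  ``groups`` has mean, SE (= sd/sqrt(n))
        and n per (group, parameter), plus ``pct_change_vs_<reference>``
        when a reference is given.
    """
    from phytojip.phenomics import percent_change

    rows = []
    for curve in curves:
        row: dict = {"label": curve.label}
        if group_by is not None:
            row[group_by] = curve.metadata.get(group_by)
        try:
            markers = extract_markers(curve, config)
            params = analyze_transient(curve, config)
        except (DegenerateTransientError, UndefinedRatioError,
                CurveValidationError) as exc:
            row.update({c: np.nan for c in _MARKER_COLS + _PARAM_COLS})
            row["flags"] = f"degenerate: {exc}"
            rows.append(row)
            continue
        row.update(zip(_MARKER_COLS,
                       (markers.fo, markers.f300, markers.fj,
                        markers.fi, markers.fm)))
        row.update({c: getattr(params, c) for c in _PARAM_COLS})
        row["flags"] = "; ".join(params.flags)
        rows.append(row)
    per_curve = pd.DataFrame(rows)

    if group_by is None:
        return per_curve, None
    valid = per_curve[~per_curve["flags"].str.startswith("degenerate")]
    n_excluded = len(per_curve) - len(valid)
    if n_excluded:
        import logging

        logging.getLogger(__name__).warning(
            "excluded %d degenerate transient(s) from group summary",
            n_excluded,
        )
    long = valid.melt(
        id_vars=[group_by], value_vars=_PARAM_COLS,
        var_name="parameter", value_name="value",
    )
    g = long.groupby([group_by, "parameter"])["value"]
    groups = g.agg(n="count", mean="mean", sd="std").reset_index()
    groups["se"] = groups["sd"] / np.sqrt(groups["n"])
    groups.loc[groups["n"] == 1, "se"] = 0.0
    if reference is not None:
        ref = groups[groups[group_by] == reference].set_index("parameter")[
            "mean"
        ]
        if ref.empty:
            raise ValueError(f"reference group {reference!r} not found")
        groups[f"pct_change_vs_{reference}"] = [
            percent_change(m, ref[p])
            for m, p in zip(groups["mean"], groups["parameter"])
        ]
    return per_curve, groups


def replace_markers(markers: OJIPMarkers, **kwargs) -> OJIPMarkers:
    """Return markers with selected fields replaced (convenience)."""
    return replace(markers, **kwargs)
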