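"""820 nm transmittance (P700 redox) kinetics.

Under strong actinic light the transmitted 830/820 nm measuring beam
tracks the redox state of P700, the primary electron donor of PSI:
oxidation of P700 lowers transmittance, re-reduction by intersystem
electrons restores it.  Curves are normalized to their first sample and
reduced to the minimal statistics supporting group comparisons — the
oxidation amplitude (1 - minimum), the time of the minimum, and the
final recovery level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NORMALIZED_TOL = 1e-6


@dataclass(frozen=True)
class TransmittanceCurve:
    """A sampled 820 nm transmittance kinetic (instrument units > 0)."""

    times: np.ndarray
    i820: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.i820, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and i820 must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError("i820 values must be finite and positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "i820", v)

    @property
    def is_normalized(self) -> bool:
        return abs(self.i820[0] - 1.0) <= NORMALIZED_TOL


def read_transmittance(path, time_unit: str = "s", label=None,
                       metadata=None) -> TransmittanceCurve:
    """Read a two-column (time, I820) delimited file.

    Same dialect as :func:`phytojip.curves.read_transient`, but without
    the fluorescence-specific span/size requirements.
    """
    from phytojip.curves import read_transient

    # reuse the transient reader's parsing/validation, then rewrap
    curve = read_transient(path, time_unit, label=label, metadata=metadata)
    return TransmittanceCurve(curve.times, curve.values, curve.label,
                              dict(curve.metadata))


def normalize_transmittance(curve: TransmittanceCurve) -> TransmittanceCurve:
    """Divide all samples by the first one so the curve starts at 1."""
    first = curve.i820[0]
    if first <= 0:
        raise ValueError("first sample must be positive to normalize")
    return TransmittanceCurve(
        curve.times, curve.i820 / first, curve.label, dict(curve.metadata)
    )


def oxidation_amplitude(
    curve: TransmittanceCurve, smooth: int = 3
) -> tuple[float, float]:
    """P700 oxidation amplitude of a normalized transmittance curve.

    Returns ``(1 - min(I/I0), t_min)``; larger amplitude means stronger
    P700 oxidation.  The minimum is located on the sampled grid after a
    centered moving-average of ``smooth`` points: transmittance valleys
    are broad, so the raw pointwise minimum of a noisy record is biased
    low by noise selection, while a short moving average leaves the
    smooth underlying kinetic essentially unchanged.  ``smooth=1``
    recovers the raw-grid minimum.

    Raises
    ------
    ValueError
        If the curve is not normalized (first value != 1 within 1e-6).
    """
    if not curve.is_normalized:
        raise ValueError(
            f"curve {curve.label!r} is not normalized "
            f"(first value {curve.i820[0]:g}); "
            "call normalize_transmittance first"
        )
    if smooth < 1 or smooth % 2 == 0:
        raise ValueError("smooth must be an odd positive window size")
    y = curve.i820
    t = curve.times
    if smooth > 1 and y.size > smooth:
        kernel = np.full(smooth, 1.0 / smooth)
        y = np.convolve(y, kernel, mode="valid")
        t = t[smooth // 2: smooth // 2 + y.size]
    i_min = int(np.argmin(y))
    return 1.0 - float(y[i_min]), float(t[i_min])


def recovery_level(curve: TransmittanceCurve) -> float:
    """Final (last-sample) transmittance of a normalized curve."""
    if not curve.is_normalized:
        raise ValueError("curve is not normalized")
    return float(curve.i820[-1])


def rank_groups_by_transmittance(
    groups: dict[str, list[TransmittanceCurve]],
) -> list[tuple[str, float, bool]]:
    """Order groups by mean minimum transmittance, lowest first.

    Lowest minimum = strongest P700 oxidation.  Returns
    ``[(group, mean_min, tied), ...]`` sorted ascending by mean minimum;
    exact ties are broken lexicographically and flagged via ``tied``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to rank")
    means: dict[str, float] = {}
    for name, curves in groups.items():
        if not curves:
            raise ValueError(f"group {name!r} is empty")
        mins = []
        for c in curves:
            if not c.is_normalized:
                raise ValueError(
                    f"curve {c.label!r} in group {name!r} is not normalized"
                )
            mins.append(float(np.min(c.i820)))
        means[name] = float(np.mean(mins))
    ordered = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    values = [v for _, v in ordered]
    return [
        (name, value, values.count(value) > 1)
        for name, value in ordered
    ]
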