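"""Relative transcript abundance by the comparative-Ct (ddCt) method.

For each sample, replicate Ct values of the target and reference genes
are averaged; dCt = mean Ct_target - mean Ct_reference; ddCt subtracts
the calibrator sample's dCt; and the relative quantity is
RQ = 2^-ddCt, assuming perfect doubling per cycle.  For display the
RQ is log-transformed (base 10 by default, base 2 optionally).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample", "gene", "role", "ct"]
CT_MAX = 45.0


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format Ct table (sample, gene, role, ct).

    ``role`` is ``"target"`` or ``"reference"``; one row per replicate
    well.  Ct values must lie in (0, 45).
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    table = table[CT_COLUMNS].copy()
    bad_roles = set(table["role"]) - {"target", "reference"}
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    table["ct"] = pd.to_numeric(table["ct"], errors="raise")
    if not np.all((table["ct"] > 0) & (table["ct"] < CT_MAX)):
        raise ValueError(f"Ct values must lie in (0, {CT_MAX:g})")
    return table


def relative_expression(
    table: pd.DataFrame, calibrator: str, log_base: int = 10
) -> pd.DataFrame:
    """Per-sample ddCt relative expression against a calibrator sample.

    Parameters
    ----------
    table
        Long-format Ct table (see :func:`validate_ct_table`); replicate
        Cts are averaged per (sample, role) before differencing.
    calibrator
        Sample label whose dCt anchors the scale; its RQ is exactly 1.
    log_base
        Base of the display transform column ``log_rq`` (10 or 2).

    Returns
    -------
    DataFrame with columns sample, dct, ddct, rq, log_rq.
    """
    table = validate_ct_table(table)
    means = (
        table.groupby(["sample", "role"])["ct"].mean().unstack("role")
    )
    for role in ("target", "reference"):
        if role not in means.columns or means[role].isna().any():
            bad = (means.index.tolist() if role not in means.columns
                   else means.index[means[role].isna()].tolist())
            raise ValueError(f"samples missing {role} gene Cts: {bad}")
    if calibrator not in means.index:
        raise ValueError(f"calibrator sample {calibrator!r} not found")
    dct = means["target"] - means["reference"]
    ddct = dct - dct[calibrator]
    rq = np.power(2.0, -ddct)
    out = pd.DataFrame({
        "sample": means.index,
        "dct": dct.values,
        "ddct": ddct.values,
        "rq": rq.values,
    })
    out["log_rq"] = [display_transform(v, log_base) for v in out["rq"]]
    return out.reset_index(drop=True)


def display_transform(rq: float, base: int = 10) -> float:
    """Display transform log_base(RQ) of a relative quantity."""
    if rq <= 0:
        raise ValueError("RQ must be positive")
    if base == 10:
        return math.log10(rq)
    if base == 2:
        return math.log2(rq)
    raise ValueError("base must be 2 or 10")
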