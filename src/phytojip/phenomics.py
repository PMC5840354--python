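"""Agronomic/ionic trait statistics for genotype-by-treatment designs.

Long-format trait tables (genotype, treatment, replicate, trait, value)
are summarized as mean +/- SE per group, compared by percent change,
Student's t-test, or one-way ANOVA followed by Fisher's protected LSD
pairwise procedure.  Helper ratios cover the standard seedling stress
assays: germination percentage, shoot K+/Na+ ratio, and electrolyte
leakage (initial over total conductivity, a membrane-damage index).

A transcribed yield-trait reference table (three rice genotypes — wild
type, an intermediate-filament overexpressor, and its knock-down — under
control, salinity and heat treatments) ships with the package for demos
and report formatting; see :func:`load_yield_traits`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = ["genotype", "treatment", "replicate", "trait", "value"]
GROUP_KEYS = ["genotype", "treatment", "trait"]


# ---------------------------------------------------------------------------
# elementary ratios


def percent_change(value: float, reference: float) -> float:
    """Signed percent change of *value* relative to *reference*."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def percent_reduction(value: float, reference: float) -> float:
    """Percent reduction 100*(1 - value/reference); negates percent_change."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (1.0 - value / reference)


def germination_percentage(n_germinated: int, n_total: int) -> float:
    """Percent of seeds germinated."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_germinated <= n_total:
        raise ValueError("n_germinated must be in [0, n_total]")
    return 100.0 * n_germinated / n_total

def kna_ratio(k_conc: float, na_conc: float) -> float:
    """Shoot K+/Na+ concentration ratio (higher = better ion homeostasis)."""
    if na_conc <= 0:
        raise ValueError("Na+ concentration must be positive")
    return k_conc / na_conc


def electrolyte_leakage(ec_initial: float, ec_total: float) -> float:
    """Electrolyte leakage percent, 100 * EC_initial / EC_total.

    EC_initial is the conductivity of the bathing solution before, and
    EC_total after, complete tissue lysis.
    """
    if ec_total <= 0:
        raise ValueError("total conductivity must be positive")
    if not 0 <= ec_initial <= ec_total:
        raise ValueError("initial conductivity must be in [0, total]")
    return 100.0 * ec_initial / ec_total


# ---------------------------------------------------------------------------
# trait tables


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format trait table and return it with canonical dtypes.

    Requires columns genotype, treatment, replicate, trait, value; no
    duplicate (genotype, treatment, replicate, trait) keys; finite values.
    """
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    table = table[TRAIT_COLUMNS].copy()
    table["value"] = pd.to_numeric(table["value"], errors="raise")
    if not np.all(np.isfinite(table["value"])):
        raise ValueError("trait values must be finite")
    keys = ["genotype", "treatment", "replicate", "trait"]
    dup = table.duplicated(keys)
    if dup.any():
        raise ValueError(
            f"duplicate trait keys: {table.loc[dup, keys].iloc[0].to_dict()}"
        )
    return table


def read_trait_table(path) -> pd.DataFrame:
    """Read a long-format trait CSV (header as TRAIT_COLUMNS)."""
    return validate_trait_table(pd.read_csv(path))


def group_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE = sd/sqrt(n) per (genotype, treatment, trait).

    Groups with a single replicate get se = 0 and ``flag = "n=1"``.
    """
    table = validate_trait_table(table)
    if table.empty:
        raise ValueError("trait table is empty")
    g = table.groupby(GROUP_KEYS)["value"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = 0.0
    out["flag"] = np.where(out["n"] == 1, "n=1", "")
    return out.drop(columns="sd")


def load_yield_traits() -> pd.DataFrame:
    """Packaged yield-trait reference table (mean, se per group).

    Columns: genotype (WT, KDIF2, OEIF2), treatment (control, salinity,
    heat), trait, mean, se.  Salinity reproductive traits of the
    knock-down line are 0: those plants did not reach the reproductive
    phase under salt.
    """
    with resources.files("phytojip.data").joinpath(
        "yield_traits.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def yield_percent_reductions(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stress deficits computed from the packaged yield-trait table.

    Each row is a percent reduction of one genotype/treatment trait mean
    relative to a stated baseline: salt-stressed WT spikelets per panicle
    vs the salt-stressed overexpressor; heat-stressed WT and knock-down
    filled grains and total yield vs the heat-stressed overexpressor; and
    heat-stressed WT yield vs its own unstressed control.
    """
    if table is None:
        table = load_yield_traits()
    m = table.set_index(["genotype", "treatment", "trait"])["mean"]

    def cell(genotype, treatment, trait):
        return m[(genotype, treatment, trait)]

    claims = [
        ("salinity_spikelets_wt_vs_oe",
         "spikelets_per_panicle", "salinity", "WT", "OEIF2", "salinity"),
        ("heat_filled_grains_wt_vs_oe",
         "filled_spikelets_per_panicle", "heat", "WT", "OEIF2", "heat"),
        ("heat_filled_grains_kd_vs_oe",
         "filled_spikelets_per_panicle", "heat", "KDIF2", "OEIF2", "heat"),
        ("heat_yield_wt_vs_oe",
         "total_yield_filled_grains", "heat", "WT", "OEIF2", "heat"),
        ("heat_yield_kd_vs_oe",
         "total_yield_filled_grains", "heat", "KDIF2", "OEIF2", "heat"),
        ("heat_yield_wt_vs_wt_control",
         "total_yield_filled_grains", "heat", "WT", "WT", "control"),
    ]
    rows = []
    for name, trait, trt, geno, ref_geno, ref_trt in claims:
        value = cell(geno, trt, trait)
        reference = cell(ref_geno, ref_trt, trait)
        rows.append({
            "claim": name,
            "trait": trait,
            "value": value,
            "reference": reference,
            "percent_reduction": percent_reduction(value, reference),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float  # pooled error mean square (MSE)
    group_means: tuple[float, ...]
    group_ns: tuple[int, ...]


def one_way_anova(groups: list[np.ndarray | list[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Explicit between/within sums-of-squares decomposition; the error
    mean square and degrees of freedom are exposed for the protected LSD
    procedure.  F is defined as 0 when both the between- and
    within-group sums of squares vanish (all observations identical).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    ns = np.array([g.size for g in arrays])
    n_total = int(ns.sum())
    k = len(arrays)
    means = np.array([g.mean() for g in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2)
                          for g, m in zip(arrays, means)))
    df_b, df_w = k - 1, n_total - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        if ss_between == 0.0:
            f = 0.0
            p = 1.0
        else:
            f = math.inf
            p = 0.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f=f, p=p, df_between=df_b, df_within=df_w, ms_within=ms_w,
        group_means=tuple(means), group_ns=tuple(int(n) for n in ns),
    )


def protected_lsd(
    groups: list[np.ndarray | list[float]], alpha: float = 0.05
) -> tuple[AnovaResult, np.ndarray]:
    """Fisher's protected least-significant-difference procedure.

    The pairwise LSD test is applied only when the omnibus ANOVA is
    significant at *alpha* ("protected"); otherwise every pair is
    declared not significant.  Pair (i, j) is significant when
    ``|mean_i - mean_j| > t(1 - alpha/2, df_within) *
    sqrt(MSE * (1/n_i + 1/n_j))``.

    Returns the ANOVA result and a boolean k x k decision matrix
    (diagonal False).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    anova = one_way_anova(groups)
    k = len(anova.group_means)
    decisions = np.zeros((k, k), dtype=bool)
    if anova.p >= alpha:
        return anova, decisions
    t_crit = stats.t.ppf(1 - alpha / 2, anova.df_within)
    for i in range(k):
        for j in range(i + 1, k):
            lsd = t_crit * math.sqrt(
                anova.ms_within
                * (1 / anova.group_ns[i] + 1 / anova.group_ns[j])
            )
            sig = abs(anova.group_means[i] - anova.group_means[j]) > lsd
            decisions[i, j] = decisions[j, i] = sig
    return anova, decisions


def two_sample_t(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, float]:
    """Student's t-test (two-sided).

    Unpaired tests pool the variance (classical Student); ``welch=True``
    drops the equal-variance assumption.  Paired tests require equal
    lengths.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
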