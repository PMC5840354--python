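"""GC-MS metabolite statistics: normalization, fold change, PCA.

The chain mirrors standard untargeted GC-MS practice: divide each
sample's peak intensities by its spiked internal standard (ribitol) to
correct extraction/injection variation; log-transform for distribution
checks; form per-time-point log2 stress/control fold changes from group
means; classify metabolites as increased/decreased per genotype and
intersect the sets Venn-style; and run unsupervised PCA for an overview
of the variance structure.  Box-whisker summaries use mean +/- 1.96*sd
(approximate 95% interval under normality), not quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["sample", "genotype", "condition", "timepoint", "replicate"]
DEFAULT_STANDARD = "ribitol"


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity matrix with sample metadata.

    ``data`` holds nonnegative intensities indexed by sample id;
    ``meta`` carries genotype, condition (control/stress), timepoint and
    replicate per sample; ``internal_standard`` names the spiked
    compound's column.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    internal_standard: str = DEFAULT_STANDARD
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.internal_standard not in self.data.columns:
            raise ValueError(
                f"internal standard column {self.internal_standard!r} missing"
            )
        missing_meta = [c for c in META_COLUMNS[1:] if c not in self.meta.columns]
        if missing_meta:
            raise ValueError(f"sample metadata missing: {missing_meta}")
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the sample index")
        if self.meta[["genotype", "condition", "timepoint", "replicate"]] \
                .duplicated().any():
            raise ValueError("replicate keys must be unique")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.data.columns if c != self.internal_standard]


def read_metabolite_matrix(
    path, internal_standard: str = DEFAULT_STANDARD
) -> MetaboliteMatrix:
    """Read the CSV dialect: sample,genotype,condition,timepoint,replicate
    metadata columns followed by one column per metabolite."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metabolite CSV missing columns: {missing}")
    df = df.set_index("sample")
    meta = df[META_COLUMNS[1:]]
    data = df.drop(columns=META_COLUMNS[1:]).astype(float)
    return MetaboliteMatrix(data, meta, internal_standard)


def write_metabolite_matrix(matrix: MetaboliteMatrix, path) -> None:
    out = pd.concat([matrix.meta, matrix.data], axis=1)
    out.index.name = "sample"
    out.to_csv(path)


def normalize_internal_standard(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each sample's intensities by its internal-standard intensity."""
    std = matrix.data[matrix.internal_standard]
    bad = std.index[(std <= 0) | ~np.isfinite(std)]
    if len(bad):
        raise ValueError(
            f"nonpositive internal standard in sample(s): {list(bad)}"
        )
    data = matrix.data.div(std, axis=0)
    return MetaboliteMatrix(
        data, matrix.meta.copy(), matrix.internal_standard,
        dict(matrix.flags, normalized=True),
    )


def drop_sparse_metabolites(
    matrix: MetaboliteMatrix, max_missing_fraction: float = 0.5
) -> MetaboliteMatrix:
    """Drop metabolites absent (zero intensity) in more than the given
    fraction of samples; zeros elsewhere stay flagged-missing, never
    imputed."""
    zero_frac = (matrix.data == 0).mean(axis=0)
    keep = zero_frac <= max_missing_fraction
    keep[matrix.internal_standard] = True
    dropped = [c for c in matrix.data.columns if not keep[c]]
    return MetaboliteMatrix(
        matrix.data.loc[:, keep], matrix.meta.copy(),
        matrix.internal_standard,
        dict(matrix.flags, dropped_sparse=dropped),
    )


def log_transform(
    data: pd.DataFrame, offset: float | None = None
) -> pd.DataFrame:
    """log10(value + offset); offset defaults to 1e-9 of the matrix median."""
    values = data.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be nonnegative")
    if offset is None:
        med = float(np.median(values))
        offset = 1e-9 * med if med > 0 else 1e-12
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    return pd.DataFrame(
        np.log10(values + offset), index=data.index, columns=data.columns
    )


def fold_change_matrix(
    matrix: MetaboliteMatrix,
    genotype: str,
    stress_condition: str = "stress",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Per-time-point log2(mean stress / mean control) for one genotype.

    Computed on internal-standard-normalized data (normalization is
    applied here if the matrix is not already flagged normalized).
    Rows are metabolites, columns time points.  Entries where either
    group mean is nonpositive, or a condition is missing at a time
    point, are NaN (flagged, never silently zeroed); the flag lists are
    attached as ``result.attrs["flagged"]``.
    """
    if not matrix.flags.get("normalized"):
        matrix = normalize_internal_standard(matrix)
    meta = matrix.meta
    sel = meta["genotype"] == genotype
    if not sel.any():
        raise ValueError(f"genotype {genotype!r} not present")
    timepoints = list(dict.fromkeys(meta.loc[sel, "timepoint"]))
    mets = matrix.metabolites
    out = pd.DataFrame(index=mets, columns=timepoints, dtype=float)
    flagged: dict[str, list] = {"missing_condition": [], "nonpositive_mean": []}
    for tp in timepoints:
        s_mask = sel & (meta["timepoint"] == tp) & \
            (meta["condition"] == stress_condition)
        c_mask = sel & (meta["timepoint"] == tp) & \
            (meta["condition"] == control_condition)
        if not s_mask.any() or not c_mask.any():
            flagged["missing_condition"].append(tp)
            continue
        s_mean = matrix.data.loc[s_mask.values, mets].mean(axis=0)
        c_mean = matrix.data.loc[c_mask.values, mets].mean(axis=0)
        ok = (s_mean > 0) & (c_mean > 0)
        flagged["nonpositive_mean"].extend(
            (m, tp) for m in s_mean.index[~ok]
        )
        ratio = s_mean[ok] / c_mean[ok]
        out.loc[ratio.index, tp] = np.log2(ratio)
    out.attrs["flagged"] = flagged
    out.attrs["genotype"] = genotype
    return out


def classify_venn(
    fc_wt: pd.DataFrame,
    fc_oe: pd.DataFrame,
    threshold: float = 0.0,
    labels: tuple[str, str] = ("WT", "OEIF2"),
) -> dict:
    """Per-time-point up/down membership and Venn intersection counts.

    A metabolite is "up" for a genotype at a time point when its log2
    fold change exceeds *threshold*, "down" when below -threshold
    (threshold 0 = sign rule; NaN entries are neither).  Returns, per
    time point and per direction, the exclusive and shared membership
    lists plus their counts.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if list(fc_wt.index) != list(fc_oe.index) or \
            list(fc_wt.columns) != list(fc_oe.columns):
        raise ValueError("fold-change matrices must share both axes")
    la, lb = labels
    result: dict = {}
    for tp in fc_wt.columns:
        a, b = fc_wt[tp], fc_oe[tp]
        sets = {
            "up": (set(a.index[a > threshold]), set(b.index[b > threshold])),
            "down": (set(a.index[a < -threshold]), set(b.index[b < -threshold])),
        }
        tp_out = {}
        for direction, (sa, sb) in sets.items():
            tp_out[direction] = {
                f"{la}_only": sorted(sa - sb),
                f"{lb}_only": sorted(sb - sa),
                "shared": sorted(sa & sb),
                "counts": {
                    f"{la}_only": len(sa - sb),
                    f"{lb}_only": len(sb - sa),
                    "shared": len(sa & sb),
                },
            }
        result[tp] = tp_out
    return result


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    explained_variance_fraction: np.ndarray


def pca(
    data: pd.DataFrame, scale: bool = True, n_components: int | None = None
) -> PCAResult:
    """Unsupervised principal component analysis of a samples x features
    table.

    Columns are mean-centered and, by default, scaled to unit variance
    (zero-variance columns are dropped before scaling).  Decomposition
    is by singular values of the centered matrix; explained-variance
    fractions sum to 1 over all components and the scores' sample
    covariance is diagonal.
    """
    x = data.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if np.isnan(x).any():
        raise ValueError("missing entries must be handled before PCA")
    centered = x - x.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("matrix has zero total variance")
    centered = centered[:, keep]
    columns = data.columns[keep]
    if scale:
        centered = centered / sd[keep]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = min(centered.shape[0] - 1, centered.shape[1])
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    var = s**2
    total = np.sum(
        np.linalg.svd(centered, compute_uv=False)[:rank] ** 2
    )
    names = [f"PC{i + 1}" for i in range(s.size)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=data.index, columns=names),
        loadings=pd.DataFrame(vt.T, index=columns, columns=names),
        explained_variance_fraction=var / total,
    )


def box_whisker_summary(groups: dict[str, np.ndarray | list]) -> pd.DataFrame:
    """Mean and 1.96*sd whisker half-width per group.

    The whiskers delimit an approximate 95% interval for individual
    observations under normality.  Groups with n < 2 are flagged and get
    whisker NaN.
    """
    rows = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            rows.append({"group": name, "n": v.size,
                         "mean": float(v.mean()) if v.size else np.nan,
                         "whisker": np.nan, "flag": "n<2"})
            continue
        rows.append({
            "group": name, "n": v.size, "mean": float(v.mean()),
            "whisker": 1.96 * float(v.std(ddof=1)), "flag": "",
        })
    return pd.DataFrame(rows)
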