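"""Seeded generators for every input kind, with known ground truth.

Each generator is a pure function of its configuration and seed, and
returns the dataset together with a JSON-serializable ground-truth
record sufficient to score parameter recovery.

The OJIP generator builds transients as a weighted sum of Hill-type
sigmoids in time,

    F(t) = Fo + (Fm - Fo) * sum_k w_k / (1 + (tau_k / t)^h_k),

one component per O-J, J-I and I-P phase.  This is a geometric model of
the phase structure, not a mechanistic PSII model: its virtue is that
the relative variable fluorescence V(t) is known in closed form at any
time, so marker extraction and JIP parameters have exact recovery
oracles.  Noise is multiplicative Gaussian (instrument-like gain/shot
noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phytojip.curves import InductionCurve
from phytojip.p700 import TransmittanceCurve

# ---------------------------------------------------------------------------
# OJIP fluorescence transients


@dataclass(frozen=True)
class OJIPGenConfig:
    """Generator settings for one OJIP transient.

    Defaults give a healthy-leaf transient: Fo/Fm = 0.2 (Fv/Fm = 0.8),
    phase weights 0.5/0.25/0.25 with half-times 0.4 ms / 10 ms / 100 ms,
    118 log-spaced points from 10 us to 1 s, and 1% multiplicative
    noise.
    """

    fo: float = 500.0
    fm: float = 2500.0
    weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
    half_times: tuple[float, float, float] = (4e-4, 1e-2, 1e-1)
    steepness: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_cv: float = 0.01
    n_points: int = 118
    t_min: float = 1e-5
    t_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.fm > self.fo > 0:
            raise ValueError("require Fm > Fo > 0")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")
        tj, ti, tp = self.half_times
        if not 0 < tj < ti < tp:
            raise ValueError("half-times must satisfy 0 < tauJ < tauI < tauP")
        if any(h < 1 for h in self.steepness):
            raise ValueError("steepness values must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_points < 20:
            raise ValueError("n_points must be >= 20")


def ojip_v_true(config: OJIPGenConfig, t: float | np.ndarray) -> np.ndarray:
    """Closed-form noise-free V(t) of the generator model."""
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t)
    for w, tau, h in zip(config.weights, config.half_times, config.steepness):
        v = v + w / (1.0 + (tau / t) ** h)
    return v


def generate_ojip(
    config: OJIPGenConfig = OJIPGenConfig(),
    seed: int = 0,
    label: str = "",
    metadata: dict | None = None,
) -> tuple[InductionCurve, dict]:
    """One synthetic OJIP transient plus its ground-truth record."""
    rng = np.random.default_rng(seed)
    t = np.logspace(
        np.log10(config.t_min), np.log10(config.t_max), config.n_points
    )
    v = ojip_v_true(config, t)
    f = config.fo + (config.fm - config.fo) * v
    if config.noise_cv > 0:
        f = f * (1.0 + rng.normal(0.0, config.noise_cv, size=f.shape))
    f = np.maximum(f, 1e-6)  # keep strictly positive at extreme noise
    curve = InductionCurve(t, f, label or f"ojip_seed{seed}",
                           metadata or {})
    truth = {
        "fo": config.fo,
        "fm": config.fm,
        "fv_fm": 1.0 - config.fo / config.fm,
        "weights": list(config.weights),
        "half_times": list(config.half_times),
        "steepness": list(config.steepness),
        "v_at_2ms": float(ojip_v_true(config, 2e-3)),
        "v_at_30ms": float(ojip_v_true(config, 30e-3)),
        "noise_cv": config.noise_cv,
        "seed": seed,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# 820 nm transmittance


@dataclass(frozen=True)
class P700GenConfig:
    """Generator settings for an 820 nm transmittance kinetic.

    The normalized signal is ``I(t)/I0 = 1 - A (1 - exp(-t/tau_ox))
    exp(-t/tau_red)``: P700 oxidation pulls transmittance down with time
    constant tau_ox, re-reduction restores it with tau_red.  Defaults
    (tau_ox = 5 ms, tau_red = 2 s) separate the two phases enough that
    the realized minimum depth is within 2% of the nominal amplitude A.
    """

    amplitude: float = 0.05
    tau_ox: float = 0.005
    tau_red: float = 2.0
    noise_cv: float = 0.002
    n_points: int = 118
    t_min: float = 1e-5
    t_max: float = 1.0
    i0: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1)")
        if not 0 < self.tau_ox < self.tau_red:
            raise ValueError("require 0 < tau_ox < tau_red")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def p700_true(config: P700GenConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form noise-free normalized transmittance I(t)/I0."""
    t = np.asarray(t, dtype=float)
    a = config.amplitude
    return 1.0 - a * (1.0 - np.exp(-t / config.tau_ox)) * np.exp(
        -t / config.tau_red
    )


def p700_true_minimum(config: P700GenConfig, n_dense: int = 200_001
                      ) -> tuple[float, float]:
    """(minimum value, argmin time) of the noise-free model by dense
    evaluation on a fine log grid — the oracle for amplitude recovery."""
    t = np.logspace(
        np.log10(config.t_min), np.log10(config.t_max), n_dense
    )
    y = p700_true(config, t)
    i = int(np.argmin(y))
    return float(y[i]), float(t[i])


def generate_820(
    config: P700GenConfig = P700GenConfig(),
    seed: int = 0,
    label: str = "",
    metadata: dict | None = None,
) -> tuple[TransmittanceCurve, dict]:
    """One synthetic 820 nm transmittance curve plus ground truth."""
    rng = np.random.default_rng(seed)
    t = np.logspace(
        np.log10(config.t_min), np.log10(config.t_max), config.n_points
    )
    y = p700_true(config, t) * config.i0
    if config.noise_cv > 0:
        y = y * (1.0 + rng.normal(0.0, config.noise_cv, size=y.shape))
    y = np.maximum(y, 1e-9)
    curve = TransmittanceCurve(t, y, label or f"p700_seed{seed}",
                               metadata or {})
    min_true, t_min_true = p700_true_minimum(config)
    truth = {
        "amplitude": config.amplitude,
        "tau_ox": config.tau_ox,
        "tau_red": config.tau_red,
        "true_minimum": min_true,
        "true_t_min": t_min_true,
        "realized_amplitude": 1.0 - min_true,
        "noise_cv": config.noise_cv,
        "seed": seed,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# trait tables


@dataclass(frozen=True)
class TraitGenConfig:
    """Generator settings for a long-format trait table.

    ``group_params`` maps (genotype, treatment, trait) to (mean, se);
    by default the packaged yield-trait reference table.  Replicate
    values are mean + Normal(0, (se*sqrt(n))^2): the configured se is
    the standard error of the group mean at the configured n (default
    n = 9, three biological x three technical replicates).
    """

    group_params: dict = field(default_factory=dict)
    n_per_group: int = 9

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for key, (mean, se) in self.group_params.items():
            if se < 0:
                raise ValueError(f"negative SE for group {key}")


def default_trait_config(n_per_group: int = 9) -> TraitGenConfig:
    """TraitGenConfig seeded from the packaged yield-trait table."""
    from phytojip.phenomics import load_yield_traits

    table = load_yield_traits()
    params = {
        (r.genotype, r.treatment, r.trait): (float(r.mean), float(r.se))
        for r in table.itertuples()
    }
    return TraitGenConfig(group_params=params, n_per_group=n_per_group)


def generate_traits(
    config: TraitGenConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """A long-format trait table plus the generating means/SEs."""
    if config is None or not config.group_params:
        config = default_trait_config(
            config.n_per_group if config else 9
        )
    rng = np.random.default_rng(seed)
    n = config.n_per_group
    rows = []
    for (genotype, treatment, trait), (mean, se) in sorted(
        config.group_params.items()
    ):
        sd = se * np.sqrt(n)
        values = mean + rng.normal(0.0, sd, size=n) if sd > 0 \
            else np.full(n, mean)
        for rep, value in enumerate(values, start=1):
            rows.append({
                "genotype": genotype, "treatment": treatment,
                "replicate": rep, "trait": trait, "value": float(value),
            })
    table = pd.DataFrame(rows)
    truth = {
        "n_per_group": n,
        "groups": {
            f"{g}|{t}|{tr}": {"mean": m, "se": s}
            for (g, t, tr), (m, s) in sorted(config.group_params.items())
        },
        "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_ct(
    rq_true: dict[str, float],
    calibrator: str,
    ct_ref_mean: float = 20.0,
    dct_calibrator: float = 2.0,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic Ct table with programmed relative quantities.

    Reference-gene Cts are Normal(ct_ref_mean, noise_sd^2); target Cts
    are the reference mean plus the calibrator dCt minus log2 of the
    programmed RQ, plus noise.  ddCt analysis recovers ``rq_true`` in
    expectation; the calibrator must be in ``rq_true`` with RQ 1.
    """
    if calibrator not in rq_true:
        raise ValueError("calibrator must appear in rq_true")
    if any(v <= 0 for v in rq_true.values()):
        raise ValueError("programmed RQ values must be positive")
    if replicates < 1 or noise_sd < 0:
        raise ValueError("invalid replicates/noise_sd")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in sorted(rq_true):
        # ddCt = dct_sample - dct_calibrator = -log2(RQ)
        dct = dct_calibrator - np.log2(rq_true[sample] / rq_true[calibrator])
        for _ in range(replicates):
            rows.append({"sample": sample, "gene": "reference_gene",
                         "role": "reference",
                         "ct": ct_ref_mean + rng.normal(0, noise_sd)})
            rows.append({"sample": sample, "gene": "target_gene",
                         "role": "target",
                         "ct": ct_ref_mean + dct + rng.normal(0, noise_sd)})
    table = pd.DataFrame(rows)
    truth = {"rq_true": dict(rq_true), "calibrator": calibrator,
             "noise_sd": noise_sd, "replicates": replicates, "seed": seed}
    return table, truth


# ---------------------------------------------------------------------------
# metabolite matrices


@dataclass(frozen=True)
class MetabGenConfig:
    """Generator settings for a samples x metabolites matrix.

    ``effects`` maps time point -> {metabolite_name: log2 effect}; a
    positive effect raises the stress mean of that metabolite by that
    many log2 units at that time point.  Intensities are
    ``2**(baseline + effect*1[stress]) * loading * (1 + noise)``, with a
    per-sample loading factor emulating extraction/injection variation
    that internal-standard normalization must remove; the internal
    standard column equals the loading alone.
    """

    n_metabolites: int = 40
    effects: dict = field(default_factory=dict)
    timepoints: tuple[str, ...] = ("24h", "48h", "72h")
    genotypes: tuple[str, ...] = ("WT", "OEIF2")
    replicates: int = 3
    cv: float = 0.10
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)
    loading_range: tuple[float, float] = (0.5, 2.0)
    internal_standard: str = "ribitol"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        # one signed effect per metabolite per time point keeps the
        # programmed up/down sets disjoint by construction
        for tp in self.effects:
            if tp not in self.timepoints:
                raise ValueError(f"effects reference unknown time point {tp!r}")


def generate_metabolites(
    config: MetabGenConfig = MetabGenConfig(), seed: int = 0
):
    """Synthetic metabolite matrix plus programmed up/down truth sets.

    Effects apply to every genotype in ``config.genotypes`` (genotype-
    specific designs can be generated per genotype and concatenated).
    Returns (MetaboliteMatrix, truth) where truth lists the up and down
    metabolite sets per time point.
    """
    from phytojip.metabolomics import MetaboliteMatrix

    rng = np.random.default_rng(seed)
    names = [f"met{i:03d}" for i in range(config.n_metabolites)]
    baseline = rng.uniform(*config.baseline_log2_range,
                           size=config.n_metabolites)
    rows, meta_rows, index = [], [], []
    for genotype in config.genotypes:
        for condition in ("control", "stress"):
            for tp in config.timepoints:
                eff = config.effects.get(tp, {})
                log2_mean = baseline.copy()
                if condition == "stress":
                    for m, e in eff.items():
                        log2_mean[names.index(m)] += e
                for rep in range(1, config.replicates + 1):
                    loading = rng.uniform(*config.loading_range)
                    intensity = np.exp2(log2_mean) * loading
                    if config.cv > 0:
                        intensity = intensity * (
                            1.0 + rng.normal(0, config.cv, size=intensity.shape)
                        )
                    intensity = np.maximum(intensity, 0.0)
                    sample = f"{genotype}_{condition}_{tp}_r{rep}"
                    index.append(sample)
                    rows.append(
                        np.concatenate([intensity, [loading]])
                    )
                    meta_rows.append({
                        "genotype": genotype, "condition": condition,
                        "timepoint": tp, "replicate": rep,
                    })
    data = pd.DataFrame(
        rows, index=pd.Index(index, name="sample"),
        columns=names + [config.internal_standard],
    )
    meta = pd.DataFrame(meta_rows, index=data.index)
    matrix = MetaboliteMatrix(data, meta, config.internal_standard)
    truth = {
        "up": {tp: sorted(m for m, e in config.effects.get(tp, {}).items()
                          if e > 0)
               for tp in config.timepoints},
        "down": {tp: sorted(m for m, e in config.effects.get(tp, {}).items()
                            if e < 0)
                 for tp in config.timepoints},
        "effects": {tp: dict(eff) for tp, eff in config.effects.items()},
        "cv": config.cv,
        "seed": seed,
    }
    return matrix, truth
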