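"""End-to-end demo pipeline: simulate -> analyze -> report.

A run is described by a YAML/dict configuration with a single top-level
seed; each requested stage generates its synthetic inputs, runs the
matching analysis module, and writes CSV/JSON outputs under one run
directory with a MANIFEST listing every file and its producing stage.
The JSON summary always includes the yield-trait percent-reduction
block computed from the packaged reference table.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("phytojip.pipeline")

ALL_STAGES = ("ojip", "p700", "traits", "qpcr", "metabolites")


@dataclass
class RunConfig:
    """Pipeline run settings.

    ``stages`` lists which analyses to run (default: all); ``alpha`` is
    the significance level for trait comparisons; ``seed`` drives every
    generator through per-stage substreams.
    """

    out_dir: Path = Path("phytojip_run")
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    alpha: float = 0.05
    reference_group: str = "WT"
    n_replicates: int = 6
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    # independent substream per stage, stable across stage selections
    return int(
        np.random.SeedSequence([seed, ALL_STAGES.index(stage)])
        .generate_state(1)[0] % (2**31)
    )


def _log(stage: str, message: str) -> None:
    logger.info("[%s] %s", stage, message)


def _run_ojip(config: RunConfig, out: Path, manifest: list) -> dict:
    from phytojip.ojip import jip_summary
    from phytojip.synthetic import OJIPGenConfig, generate_ojip

    seed = _stage_seed(config.seed, "ojip")
    scenarios = {
        "control": OJIPGenConfig(),
        "salinity": OJIPGenConfig(fo=520.0, fm=2300.0,
                                  weights=(0.55, 0.25, 0.20)),
    }
    curves = []
    for i, (treatment, gen) in enumerate(scenarios.items()):
        for rep in range(config.n_replicates):
            curve, _ = generate_ojip(
                gen, seed=seed + 100 * i + rep,
                label=f"{treatment}_r{rep + 1}",
                metadata={"treatment": treatment},
            )
            curves.append(curve)
    per_curve, groups = jip_summary(
        curves, group_by="treatment", reference="control"
    )
    per_curve.to_csv(out / "jip_per_curve.csv", index=False)
    groups.to_csv(out / "jip_groups.csv", index=False)
    manifest += [("ojip", "jip_per_curve.csv"), ("ojip", "jip_groups.csv")]
    _log("ojip", f"analyzed {len(curves)} transients "
                 f"-> {len(per_curve)} rows, {len(groups)} group stats")
    pi = groups[groups["parameter"] == "pi_abs"].set_index("treatment")
    return {
        "n_curves": len(curves),
        "pi_abs_mean_by_treatment": pi["mean"].to_dict(),
        "pi_abs_pct_change_vs_control":
            pi["pct_change_vs_control"].to_dict(),
    }


def _run_p700(config: RunConfig, out: Path, manifest: list) -> dict:
    from phytojip.p700 import (
        normalize_transmittance,
        oxidation_amplitude,
        rank_groups_by_transmittance,
    )
    from phytojip.synthetic import P700GenConfig, generate_820

    seed = _stage_seed(config.seed, "p700")
    amplitudes = {"OEIF2": 0.07, "KDIF2": 0.05, "WT": 0.03}
    groups, rows = {}, []
    for i, (genotype, a) in enumerate(amplitudes.items()):
        gen = P700GenConfig(amplitude=a)
        curves = []
        for rep in range(config.n_replicates):
            curve, _ = generate_820(gen, seed=seed + 100 * i + rep,
                                    label=f"{genotype}_r{rep + 1}")
            norm = normalize_transmittance(curve)
            amp, t_min = oxidation_amplitude(norm)
            rows.append({"genotype": genotype, "curve": curve.label,
                         "amplitude": amp, "t_min": t_min})
            curves.append(norm)
        groups[genotype] = curves
    ranking = rank_groups_by_transmittance(groups)
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "p700_amplitudes.csv", index=False)
    manifest.append(("p700", "p700_amplitudes.csv"))
    _log("p700", f"ranked {len(groups)} groups over "
                 f"{len(rows)} curves")
    return {"ranking_lowest_transmittance_first":
            [name for name, _, _ in ranking]}


def _run_traits(config: RunConfig, out: Path, manifest: list) -> dict:
    from phytojip.phenomics import (
        group_summaries,
        protected_lsd,
        yield_percent_reductions,
    )
    from phytojip.synthetic import generate_traits

    seed = _stage_seed(config.seed, "traits")
    table, _ = generate_traits(seed=seed)
    table.to_csv(out / "traits.csv", index=False)
    summaries = group_summaries(table)
    summaries.to_csv(out / "trait_summaries.csv", index=False)
    manifest += [("traits", "traits.csv"), ("traits", "trait_summaries.csv")]

    # protected LSD across genotypes for heat-stress yield
    yield_trait = "total_yield_filled_grains"
    sub = table[(table["treatment"] == "heat")
                & (table["trait"] == yield_trait)]
    genotypes = sorted(sub["genotype"].unique())
    anova, decisions = protected_lsd(
        [sub.loc[sub["genotype"] == g, "value"].to_numpy()
         for g in genotypes],
        alpha=config.alpha,
    )
    reductions = yield_percent_reductions()
    reductions.to_csv(out / "yield_percent_reductions.csv", index=False)
    manifest.append(("traits", "yield_percent_reductions.csv"))
    _log("traits", f"{len(table)} trait records; heat-yield ANOVA "
                   f"F={anova.f:.2f} p={anova.p:.2e}")
    return {
        "n_records": len(table),
        "heat_yield_anova": {"f": anova.f, "p": anova.p,
                             "genotypes": genotypes,
                             "any_pair_significant":
                                 bool(decisions.any())},
        "yield_percent_reductions": {
            r.claim: r.percent_reduction for r in reductions.itertuples()
        },
    }


def _run_qpcr(config: RunConfig, out: Path, manifest: list) -> dict:
    from phytojip.qpcr import relative_expression
    from phytojip.synthetic import generate_ct

    seed = _stage_seed(config.seed, "qpcr")
    rq_true = {"IR64_control": 1.0, "IR64_salt_48h": 4.0,
               "Pokkali_control": 4.0, "Pokkali_salt_48h": 6.0}
    table, _ = generate_ct(rq_true, calibrator="IR64_control", seed=seed)
    table.to_csv(out / "ct_values.csv", index=False)
    result = relative_expression(table, calibrator="IR64_control")
    result.to_csv(out / "relative_expression.csv", index=False)
    manifest += [("qpcr", "ct_values.csv"),
                 ("qpcr", "relative_expression.csv")]
    _log("qpcr", f"{len(table)} Ct wells -> {len(result)} samples")
    return {"rq": dict(zip(result["sample"], result["rq"]))}


def _run_metabolites(config: RunConfig, out: Path, manifest: list) -> dict:
    from phytojip.metabolomics import (
        classify_venn,
        fold_change_matrix,
        normalize_internal_standard,
        pca,
        write_metabolite_matrix,
    )
    from phytojip.synthetic import MetabGenConfig, generate_metabolites

    seed = _stage_seed(config.seed, "metabolites")
    effects = {
        "24h": {"met000": 1.5, "met001": 1.5, "met002": -1.5},
        "48h": {"met000": 2.0, "met003": 1.5, "met004": -1.5},
        "72h": {"met000": 2.0, "met005": 1.5, "met002": -2.0},
    }
    gen = MetabGenConfig(effects=effects)
    matrix, truth = generate_metabolites(gen, seed=seed)
    normalized = normalize_internal_standard(matrix)
    write_metabolite_matrix(normalized, out / "metabolites_normalized.csv")
    fc = {g: fold_change_matrix(normalized, g)
          for g in gen.genotypes}
    fc["WT"].to_csv(out / "fold_change_WT.csv")
    fc["OEIF2"].to_csv(out / "fold_change_OEIF2.csv")
    venn = classify_venn(fc["WT"], fc["OEIF2"], threshold=0.5)
    (out / "venn.json").write_text(json.dumps(venn, indent=2))
    result = pca(normalized.data[normalized.metabolites])
    result.scores.to_csv(out / "pca_scores.csv")
    result.loadings.to_csv(out / "pca_loadings.csv")
    manifest += [("metabolites", name) for name in (
        "metabolites_normalized.csv", "fold_change_WT.csv",
        "fold_change_OEIF2.csv", "venn.json", "pca_scores.csv",
        "pca_loadings.csv",
    )]
    _log("metabolites", f"{matrix.data.shape[0]} samples x "
                        f"{len(matrix.metabolites)} metabolites")
    counts = {tp: venn[tp]["up"]["counts"] for tp in venn}
    return {
        "venn_up_counts": counts,
        "pc_fractions": [float(f) for f in
                         result.explained_variance_fraction[:3]],
        "programmed_up": truth["up"],
    }


_STAGE_RUNNERS = {
    "ojip": _run_ojip,
    "p700": _run_p700,
    "traits": _run_traits,
    "qpcr": _run_qpcr,
    "metabolites": _run_metabolites,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the JSON summary (also written to ``summary.json``).  On any
    stage error the partially written run directory is removed and the
    error re-raised.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str]] = []
    summary: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "stages": list(config.stages),
    }
    t0 = time.time()
    try:
        for stage in config.stages:
            _log(stage, "starting")
            summary[stage] = _STAGE_RUNNERS[stage](config, out, manifest)
        # always include the reference-table percent-reduction block
        from phytojip.phenomics import yield_percent_reductions

        summary["yield_percent_reductions"] = {
            r.claim: r.percent_reduction
            for r in yield_percent_reductions().itertuples()
        }
        # summary.json must be byte-identical across runs of the same
        # config+seed, so wall-clock time stays out of the file
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        summary["elapsed_s"] = round(time.time() - t0, 3)
        manifest.append(("report", "summary.json"))
        (out / "MANIFEST").write_text(
            "".join(f"{stage}\t{name}\n" for stage, name in manifest)
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return summary
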