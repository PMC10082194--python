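"""Full-cohort orchestration: simulate or ingest, score, associate, report.

A run is driven by a :class:`RunConfig` holding every threshold the
scoring modules use (all defaults mirror the printed constants of the
underlying methods: 20/18 LGA bounds, 10 Mb segments, 3 Mb gaps/smoothing,
15 Mb LOH, 500 probes, 5 foci, 10% RAD51, the WES/targeted filter
thresholds and the 0.10 expression quantile).  Stage outputs are written
as TSV/JSON artifacts; the final report restates every statistic so that
it can be recomputed from the per-PDX table alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic
from .genome import load_genome
from .rad51 import score_foci_table
from .response import cohort_responses
from .scars import hrd_scar_score
from .shallow_hrd import classify_hrd, shallow_hrd_pipeline
from .stats import (
    build_contingency,
    diagnostic_metrics,
    fisher_exact_two_sided,
    km_and_gbw,
    pearson_r,
)


@dataclass
class RunConfig:
    seed: int = 0
    genome: str = "toy3"
    n_models: int = 12
    outdir: str = "hrdkit_run"
    simulate_profiles: bool = True  # recompute LGA from simulated bins
    profile_noise_sd: float = 0.05
    # printed-constant registry
    lga_hrd_gt: int = 20
    lga_hrp_lt: int = 18
    min_segment: int = 10_000_000
    max_gap: int = 3_000_000
    loh_min: int = 15_000_000
    tai_min_probes: int = 500
    lst_min: int = 10_000_000
    smooth: int = 3_000_000
    foci_threshold: int = 5
    rad51_percent_threshold: float = 10.0
    grouping: str = "cr_pr_sd_vs_pd"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # output location does not affect results
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the simulated-cohort analysis end to end.

    Returns the report dict (also written to ``outdir/report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_genome(config.genome)
    spec = dataclasses.replace(
        synthetic.CohortSpec(),
        n_models=config.n_models,
        seed=config.seed,
        profile_noise_sd=config.profile_noise_sd,
    )
    truth = synthetic.simulate_cohort_annotations(spec, seed=config.seed)
    truth.to_csv(outdir / "truth_table.tsv", sep="\t", index=False)

    # genomic HRD per model
    lga_rows = []
    cap = sum(max(0, iv.length // 10_500_000 - 1) for _, iv in genome.arms())
    for i, r in enumerate(truth.itertuples(index=False)):
        planted = min(int(r.lga_planted), cap)
        if config.simulate_profiles:
            import numpy as np

            rng = np.random.default_rng([config.seed, i])
            breaks = synthetic.plan_lga_breaks(planted, genome, rng)
            profile, _ = synthetic.simulate_binned_profile(
                breaks, genome, noise_sd=config.profile_noise_sd,
                seed=int(rng.integers(2**31)), sample_id=str(r.pdx),
            )
            _, report = shallow_hrd_pipeline(
                profile, genome, min_segment=config.min_segment, max_gap=config.max_gap
            )
            lga_total, hrd_class = report.lga_total, report.classification
        else:
            lga_total, hrd_class = planted, classify_hrd(planted)
        lga_rows.append((r.pdx, lga_total, hrd_class))
    lga_df = pd.DataFrame(lga_rows, columns=["pdx", "lga_total", "hrd_class"])

    # allelic scar scores per model
    scar_rows = []
    scar_genome = load_genome("hg19")
    for i, r in enumerate(truth.itertuples(index=False)):
        profile, _ = synthetic.simulate_allelic_profile(
            int(r.loh_planted), int(r.tai_planted), int(r.lst_planted),
            scar_genome, seed=config.seed + i, sample_id=str(r.pdx),
        )
        scores = hrd_scar_score(
            profile, scar_genome, loh_min=config.loh_min,
            tai_min_probes=config.tai_min_probes, lst_min=config.lst_min,
            smooth=config.smooth,
        )
        scar_rows.append((r.pdx, scores.loh, scores.tai, scores.lst, scores.total))
    scar_df = pd.DataFrame(scar_rows, columns=["pdx", "loh", "tai", "lst", "scar_total"])

    # tumour response from simulated growth
    measurements = synthetic.simulate_growth_cohort(truth, spec, seed=config.seed)
    measurements.to_csv(outdir / "measurements.tsv", sep="\t", index=False)
    treated = measurements[measurements["arm"] == "treated"]
    _, per_model = cohort_responses(treated)

    # RAD51 functional status
    foci = synthetic.simulate_foci_table(truth, spec, seed=config.seed)
    _, rad51_status = score_foci_table(
        foci, foci_threshold=config.foci_threshold,
        percent_threshold=config.rad51_percent_threshold,
    )

    per_pdx = (
        truth[["pdx", "true_state", "response_category", "brca_mutated_loh",
               "methylation_percent", "survival_days", "death_event"]]
        .merge(lga_df, on="pdx")
        .merge(scar_df, on="pdx")
        .merge(per_model[["pdx", "median_best_response", "median_best_avg_response", "category"]], on="pdx")
        .merge(rad51_status.rename(columns={"status": "rad51_status_called"}), on="pdx")
    )
    per_pdx["hrd_positive"] = (per_pdx["hrd_class"] == "HRD").astype(int)
    per_pdx.to_csv(outdir / "per_pdx.tsv", sep="\t", index=False)

    waterfall = per_pdx[["pdx", "median_best_avg_response", "category"]].sort_values(
        "median_best_avg_response"
    )
    waterfall.to_csv(outdir / "waterfall.csv", index=False)

    # associations
    table, excluded = build_contingency(
        per_pdx.rename(columns={"category": "response_category_called"}),
        biomarker="hrd_positive",
        grouping=config.grouping,
        response_col="response_category_called",
    )
    p = fisher_exact_two_sided(table)
    metrics = diagnostic_metrics(table)
    associations = {
        "hrd_vs_response": {
            "table": table.as_array().tolist(),
            "fisher_p": p,
            "excluded": excluded,
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv,
            "npv": metrics.npv,
        },
        "lga_vs_scar_pearson_r": pearson_r(per_pdx["lga_total"], per_pdx["scar_total"])
        if per_pdx["lga_total"].nunique() > 1 and per_pdx["scar_total"].nunique() > 1
        else None,
    }
    groups = per_pdx["category"].isin(["CR", "PR", "SD"]).map(
        {True: "responder", False: "resistant"}
    )
    if groups.nunique() == 2:
        surv = km_and_gbw(per_pdx["survival_days"], per_pdx["death_event"], groups)
        associations["survival"] = {
            "medians": surv.medians,
            "gbw_chi2": surv.statistic,
            "gbw_p": surv.p_value,
        }

    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_models": config.n_models,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "lga_hrd_gt", "lga_hrp_lt", "min_segment", "max_gap", "loh_min",
                "tai_min_probes", "lst_min", "smooth", "foci_threshold",
                "rad51_percent_threshold",
            )
        },
        "associations": associations,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
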