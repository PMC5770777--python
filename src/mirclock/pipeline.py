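"""Configuration-driven end-to-end orchestration.

Stages: simulate -> QC -> differential expression -> clock -> delta-age ->
heritability -> survival/traits -> coexpression -> targets -> enrichment.
Each stage can be toggled; every random operation is seeded from the
config; the report records every parameter actually used.  A stage failure
aborts with the stage name while partial outputs stay on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mirclock import __version__
from mirclock import io as mio
from mirclock.age_assoc import bonferroni_threshold, diffexpr_scan, replication_compare
from mirclock.clock import delta_age, predict_age, split_by_pedigree, train_clock
from mirclock.coexpr import coexpression_scan, estimate_svs
from mirclock.enrich import fisher_enrichment, hypergeom_tail_log10
from mirclock.exceptions import ConfigurationError
from mirclock.lmm import heritability, kinship_from_pedigree
from mirclock.preprocess import (
    DEFAULT_TECH_COVARIATES,
    design_matrix,
    qc_filter,
    standardized_residuals,
)
from mirclock.simulate import SimParams, simulate_cohort
from mirclock.survival import (
    ADJUST_MINIMAL,
    cox_fit,
    delta_age_tertiles,
    km_by_groups,
    trait_assoc,
)
from mirclock.targets import predicted_targets, seed_site_report

DEFAULT_STAGES = [
    "simulate",
    "qc",
    "diffexpr",
    "clock",
    "heritability",
    "survival",
    "traits",
    "coexpression",
    "targets",
    "enrichment",
]

DEFAULT_TRAITS = [
    "chd",
    "hypertension",
    "diabetes",
    "total_cholesterol",
    "hdl",
    "triglycerides",
    "sbp",
    "dbp",
    "glucose",
    "bmi",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    return cfg


def run_pipeline(config: dict | None = None, outdir: str | Path = "mirclock_out") -> dict:
    """Execute the enabled stages in dependency order; returns the report
    (also written as JSON + TSVs under ``outdir``)."""
    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", DEFAULT_STAGES)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    report: dict = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": cfg_hash,
        "stages_run": [],
    }

    sim_params = SimParams(**{**cfg.get("simulate", {}), "rng_seed": seed})
    report["sim_params"] = dataclasses.asdict(sim_params)

    state: dict = {}
    for stage in stages:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](cfg, sim_params, state, report, out, seed)
        except Exception as err:
            report["failed_stage"] = stage
            report["error"] = str(err)
            _write_report(report, out)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        report["stages_run"].append(stage)
        print(f"[mirclock] stage {stage} done in {time.time() - t0:.1f}s", file=sys.stderr)

    _write_report(report, out)
    return report


def _require(state: dict, key: str, stage: str, producer: str):
    if key not in state:
        raise ConfigurationError(
            f"stage {stage!r} needs {key!r}; enable the {producer!r} stage first"
        )
    return state[key]


def _stage_simulate(cfg, sim_params, state, report, out, seed):
    cohort = simulate_cohort(sim_params)
    cohort.to_dir(out / "synthetic")
    state["cohort"] = cohort
    state["kinship"] = kinship_from_pedigree(cohort.pedigree)
    report["simulate"] = {
        "n_samples": int(len(cohort.phenotypes)),
        "n_families": int(cohort.pedigree["pedigree_id"].nunique()),
        "n_mirna": int(cohort.ct.shape[1]),
        "n_mrna": int(cohort.mrna.shape[1]),
        "mean_age": round(float(cohort.phenotypes["age"].mean()), 2),
        "n_deaths": int(cohort.phenotypes["surv_event"].sum()),
    }


def _stage_qc(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "qc", "simulate")
    qc_cfg = cfg.get("qc", {})
    ct_qc, qrep = qc_filter(
        cohort.ct,
        limit=qc_cfg.get("limit", sim_params.detection_limit),
        outlier_sd=qc_cfg.get("outlier_sd", 5.0),
        min_expressed_frac=qc_cfg.get("min_expressed_frac", 0.95),
        max_sample_missing_frac=qc_cfg.get("max_sample_missing_frac", 0.10),
    )
    mio.write_matrix_tsv(ct_qc, out / "ct_qc.tsv")
    qrep.to_frame().to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    state["ct_qc"] = ct_qc
    report["qc"] = {line.split(":")[0]: line for line in qrep.log_lines()}
    report["qc_counts"] = {
        "kept_samples": qrep.n_kept_samples,
        "kept_mirnas": qrep.n_kept_mirnas,
        "values_filled": qrep.n_values_filled,
    }


def _stage_diffexpr(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "diffexpr", "simulate")
    ct_qc = _require(state, "ct_qc", "diffexpr", "qc")
    K = state["kinship"]
    phen = cohort.phenotypes.loc[ct_qc.index]
    covs = cfg.get("diffexpr", {}).get("covariates", ["sex"] + DEFAULT_TECH_COVARIATES)
    table = diffexpr_scan(ct_qc, phen, K, covariates=covs)
    table.to_csv(out / "diffexpr.tsv", sep="\t")
    state["diffexpr"] = table
    report["diffexpr"] = {
        "n_tested": int(table.attrs["n_tests"]),
        "bonferroni_threshold": float(table.attrs["bonferroni_threshold"]),
        "n_significant": int(table["significant"].sum()),
        "frac_down_with_age": round(
            float((table.loc[table["significant"], "beta"] > 0).mean()), 3
        )
        if table["significant"].any()
        else None,
    }


def _stage_clock(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "clock", "simulate")
    ct_qc = _require(state, "ct_qc", "clock", "qc")
    clock_cfg = cfg.get("clock", {})
    phen = cohort.phenotypes.loc[ct_qc.index]
    ped = cohort.pedigree[cohort.pedigree["individual_id"].isin(ct_qc.index)]

    split = split_by_pedigree(ped, ratio=clock_cfg.get("ratio", 0.5), seed=seed)
    train_ids = split.index[split == "A"]
    test_ids = split.index[split == "B"]
    resid_train = standardized_residuals(ct_qc.loc[train_ids], phen.loc[train_ids])
    resid_test = standardized_residuals(ct_qc.loc[test_ids], phen.loc[test_ids])

    model = train_clock(
        resid_train,
        phen.loc[train_ids, "age"],
        alpha_mix=clock_cfg.get("alpha", 0.5),
        lam=clock_cfg.get("fixed_lambda"),
        folds=clock_cfg.get("folds", 10),
        seed=seed,
        pedigree=ped,
    )
    model.save(out / "clock_model.tsv")
    pred_train, r_train = predict_age(model, resid_train, phen.loc[train_ids, "age"])
    pred_test, r_test = predict_age(model, resid_test, phen.loc[test_ids, "age"])
    dtab = delta_age(
        pd.concat([pred_train, pred_test]), phen["age"]
    )
    dtab.to_csv(out / "delta_age.tsv", sep="\t", index_label="sample_id")
    state["delta_age"] = dtab
    state["split"] = split
    report["clock"] = {
        "n_selected": int(len(model.selected)),
        "lambda": float(model.lambda_penalty),
        "alpha": float(model.alpha_mix),
        "r_train": round(r_train, 3),
        "r_test": round(r_test, 3),
        "n_train": int(len(train_ids)),
        "n_test": int(len(test_ids)),
    }


def _stage_heritability(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "heritability", "simulate")
    dtab = _require(state, "delta_age", "heritability", "clock")
    phen = cohort.phenotypes.loc[dtab.index]
    X = design_matrix(phen, ["age", "sex"])
    fit = heritability(
        dtab["delta_age"], X, K=state["kinship"].loc[dtab.index, dtab.index]
    )
    report["heritability"] = {
        "h2_delta_age": round(float(fit.h2), 3),
        "sigma2_a": round(float(fit.sigma2_a), 3),
        "sigma2_e": round(float(fit.sigma2_e), 3),
        "identifiable": bool(fit.identifiable),
    }


def _stage_survival(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "survival", "simulate")
    dtab = _require(state, "delta_age", "survival", "clock")
    phen = cohort.phenotypes.loc[dtab.index]
    X = pd.concat(
        [dtab[["delta_age"]], design_matrix(phen, ADJUST_MINIMAL, add_intercept=False)],
        axis=1,
    )
    fit = cox_fit(phen["surv_time"], phen["surv_event"], X)
    fit.summary.to_csv(out / "cox_minimal.tsv", sep="\t")
    tert = delta_age_tertiles(dtab["delta_age"])
    curves = km_by_groups(phen["surv_time"], phen["surv_event"], tert)
    km_rows = []
    for g, df in curves.items():
        df = df.assign(tertile=g)
        km_rows.append(df)
    pd.concat(km_rows).to_csv(out / "km_tertiles.tsv", sep="\t", index=False)
    d = fit.summary.loc["delta_age"]
    report["survival"] = {
        "hr_per_year": round(float(d["hr"]), 3),
        "ci95": [round(float(d["ci95_low"]), 3), round(float(d["ci95_high"]), 3)],
        "p": float(d["p"]),
        "n_events": int(fit.n_events),
    }


def _stage_traits(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "traits", "simulate")
    dtab = _require(state, "delta_age", "traits", "clock")
    K = state["kinship"]
    traits = cfg.get("traits", {}).get("list", DEFAULT_TRAITS)
    rows = []
    for trait in traits:
        res = trait_assoc(
            dtab, cohort.phenotypes, K, trait, n_traits_tested=len(traits)
        )
        rows.append({k: v for k, v in res.items() if k != "adjusted_for"})
    table = pd.DataFrame(rows).set_index("trait")
    table.to_csv(out / "trait_assoc.tsv", sep="\t")
    report["traits"] = {
        "bonferroni_threshold": bonferroni_threshold(0.05, len(traits)),
        "n_significant": int(table["significant"].sum()),
        "significant": list(table.index[table["significant"]]),
    }


def _stage_coexpression(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "coexpression", "simulate")
    ct_qc = _require(state, "ct_qc", "coexpression", "qc")
    co_cfg = cfg.get("coexpression", {})
    K = state["kinship"]
    phen = cohort.phenotypes.loc[ct_qc.index]
    mrna = cohort.mrna.loc[ct_qc.index]
    X = design_matrix(phen, ["age", "sex"] + DEFAULT_TECH_COVARIATES)
    svs = estimate_svs(mrna, X, n_sv=co_cfg.get("n_sv", 10), mirna=ct_qc)
    # keep the scan affordable: planted-coupling miRNAs plus a random rest
    n_mir = co_cfg.get("n_mirna", 25)
    n_genes = co_cfg.get("n_mrna", 100)
    rng = np.random.default_rng(seed)
    mirs = list(
        dict.fromkeys(
            [m for m in cohort.coupling["mirna_id"] if m in ct_qc.columns]
            + list(rng.permutation(ct_qc.columns))
        )
    )[:n_mir]
    genes = list(
        dict.fromkeys(
            list(cohort.coupling["mrna_id"]) + list(rng.permutation(mrna.columns))
        )
    )[:n_genes]
    table = coexpression_scan(
        ct_qc, mrna, X, K, svs=svs, mirna_ids=mirs, mrna_ids=genes
    )
    table.to_csv(out / "coexpression.tsv", sep="\t", index=False)
    state["coexpression"] = table
    report["coexpression"] = {
        "n_pairs": int(len(table)),
        "n_sv_retained": int(svs.n_sv),
        "n_fdr05": int((table["fdr"] < 0.05).sum()),
    }


def _stage_targets(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "targets", "simulate")
    sites = seed_site_report(cohort.mirna_seqs, cohort.region_seqs)
    sites.to_csv(out / "seed_sites.tsv", sep="\t", index=False)
    state["seed_sites"] = sites
    pairs = predicted_targets(sites)
    planted = set(zip(cohort.planted_sites["mirna_id"], cohort.planted_sites["mrna_id"]))
    report["targets"] = {
        "n_pairs_with_sites": int(len(pairs)),
        "planted_pairs_recovered": int(len(planted & pairs)),
        "n_planted": int(len(planted)),
    }


def _stage_enrichment(cfg, sim_params, state, report, out, seed):
    cohort = _require(state, "cohort", "enrichment", "simulate")
    co = state.get("coexpression")
    background = set(cohort.mrna.columns)
    if co is not None and (co["fdr"] < 0.05).any():
        hits = set(co.loc[co["fdr"] < 0.05, "mrna_id"])
    else:
        hits = set(cohort.coupling["mrna_id"])
    # gene sets: one planted (the coupled targets) plus random categories
    rng = np.random.default_rng(seed + 17)
    gene_sets = {"coupled_targets": sorted(set(cohort.coupling["mrna_id"]))}
    genes = list(background)
    for i in range(9):
        gene_sets[f"random_set_{i + 1}"] = sorted(
            rng.choice(genes, size=30, replace=False)
        )
    mio.write_gmt(gene_sets, out / "gene_sets.gmt")
    table = fisher_enrichment(hits, background, gene_sets)
    table.to_csv(out / "enrichment.tsv", sep="\t")
    top = table.iloc[0]
    report["enrichment"] = {
        "n_hits": int(len(hits)),
        "top_category": table.index[0],
        "top_log10_p": round(
            hypergeom_tail_log10(
                int(top["N"]), int(top["K"]), int(top["n"]), int(top["k"])
            ),
            2,
        ),
        "n_fdr05": int((table["fdr"] < 0.05).sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "diffexpr": _stage_diffexpr,
    "clock": _stage_clock,
    "heritability": _stage_heritability,
    "survival": _stage_survival,
    "traits": _stage_traits,
    "coexpression": _stage_coexpression,
    "targets": _stage_targets,
    "enrichment": _stage_enrichment,
}


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
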