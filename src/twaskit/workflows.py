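"""End-to-end study recipes on synthetic data.

These functions wire the generator, trainer, imputation and association
stages into the desk-scale experiments the package is validated on:

* :func:`power_study` - train cis models on a 500-subject panel, impute into
  a freshly drawn case-control cohort, and measure risk-gene detection,
  false positives and null inflation;
* :func:`mediation_coverage_study` - repeated gene/mediator/outcome chains
  with a known mediated proportion, checking bootstrap CI coverage;
* :func:`somatic_stratification_study` - repeated tumor cohorts with a
  germline-expression correlation confined to fusion-positive subjects.

Problem sizes default to values a single CPU handles in minutes; every
function is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cistrain import TrainingConfig, train_model_database
from .imputex import impute_transcriptome
from .somatic import stratified_correlation
from .synthdata import (
    SimulationConfig,
    TruthTable,
    gene_annotations,
    sample_case_control,
    simulate_case_control_cohort,
    simulate_expression_panel,
    simulate_genotype_panel,
    simulate_tumor_cohort,
)
from .twasassoc import compute_inflation, mediation_proportion, run_twas

_COV_COLS = ["age", "bmi", "pc1", "pc2"]


def power_study(
    seed: int,
    n_train: int = 500,
    n_genes: int = 200,
    n_cases: int = 5_000,
    n_controls: int = 5_000,
    expression_h2: float = 0.5,
    n_risk_genes: int = 10,
    risk_log_or_per_sd: float = 0.4,
) -> dict:
    """Scaled-down discovery TWAS with known risk genes.

    Trains elastic-net models (10-fold CV) on a training panel, imputes the
    transcriptome into an independently drawn population, samples the
    requested case-control cohort, and runs the association scan twice: once
    as configured and once with all risk effects zeroed (same cohort sizes)
    to measure null inflation.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_subjects=n_train,
        n_genes=n_genes,
        expression_h2=expression_h2,
        n_risk_genes=n_risk_genes,
        risk_log_or_per_sd=risk_log_or_per_sd,
    )
    train_panel = simulate_genotype_panel(cfg, cohort=0)
    expression, truth = simulate_expression_panel(train_panel, cfg)
    db, _ = train_model_database(
        train_panel,
        expression,
        gene_annotations(cfg),
        TrainingConfig(cv_scheme="kfold", seed=seed),
    )

    n_pop = int(1.25 * (n_cases + n_controls))
    cfg_pop = replace(cfg, n_subjects=n_pop)
    pop_panel = simulate_genotype_panel(cfg_pop, cohort=1)
    imputed_pop = impute_transcriptome(db, pop_panel)

    def _scan(truth_used: TruthTable, draw: int) -> tuple:
        pheno = simulate_case_control_cohort(pop_panel, truth_used, cfg_pop, draw=draw)
        rows = sample_case_control(pheno, n_cases, n_controls, seed=seed + draw)
        sub = pheno.iloc[rows]
        results, inflation, thresholds = run_twas(
            imputed_pop.values.iloc[rows],
            sub["status"].to_numpy(),
            sub[_COV_COLS],
        )
        return results, inflation, thresholds

    results, inflation, thresholds = _scan(truth, draw=0)
    significant = {r.gene_id for r in results if r.tier == "significant"}
    risk = set(truth.risk)
    null_truth = TruthTable(eqtls=truth.eqtls, risk={})
    null_results, null_inflation, _ = _scan(null_truth, draw=1)
    return {
        "n_models": len(db),
        "n_tested": len(results),
        "thresholds": thresholds,
        "risk_genes": sorted(risk),
        "risk_genes_detected": len(significant & risk),
        "false_positives": len(significant - risk),
        "lambda_1000": inflation.lambda_1000,
        "null_lambda_gc": null_inflation.lambda_gc,
        "null_lambda_1000": null_inflation.lambda_1000,
        "null_significant": sum(r.tier == "significant" for r in null_results),
    }


def mediation_coverage_study(
    seed: int,
    n_reps: int = 100,
    n_subjects: int = 6_000,
    n_boot: int = 200,
    direct_log_or: float = 0.15,
    mediator_log_or: float = 0.3,
    gene_mediator_corr: float = 0.5,
) -> dict:
    """Bootstrap-CI coverage of a configured mediated proportion.

    Each replicate draws a standardized mediator expression M, a gene
    expression X = corr * M + sqrt(1 - corr^2) * noise, and disease status
    from logit = direct_log_or * X + mediator_log_or * M. The configured
    mediated proportion of the gene's marginal signal is
    100 * (1 - a / (a + b * corr)) (50% at the defaults). Effects are kept
    small and the per-replicate sample large so the marginal log-odds is not
    materially attenuated by logistic non-collapsibility and the plug-in
    ratio estimator is effectively unbiased. Returns the fraction of
    replicates whose percentile bootstrap CI covers the configured value.
    """
    a, b, rho = direct_log_or, mediator_log_or, gene_mediator_corr
    target = 100.0 * (1.0 - a / (a + b * rho))
    rng = np.random.default_rng([seed, 8])
    covered, points = 0, []
    for rep in range(n_reps):
        m = rng.standard_normal(n_subjects)
        x = rho * m + np.sqrt(1 - rho**2) * rng.standard_normal(n_subjects)
        eta = a * x + b * m
        y = (rng.random(n_subjects) < 1 / (1 + np.exp(-eta))).astype(int)
        res = mediation_proportion(
            x, m, y, covariates=None, n_boot=n_boot, seed=seed * 1009 + rep
        )
        points.append(res.proportion_mediated)
        lo, hi = res.ci
        if np.isfinite(lo) and lo <= target <= hi:
            covered += 1
    return {
        "target_pct": target,
        "coverage": covered / n_reps,
        "n_reps": n_reps,
        "mean_point_pct": float(np.nanmean(points)),
    }


def somatic_stratification_study(
    seed: int,
    n_reps: int = 200,
    n_subjects: int = 400,
    fusion_corr: float = 0.3,
) -> dict:
    """Detection/type-I rates for the fusion-stratified correlation.

    Each replicate simulates a tumor cohort in which the germline genetic
    score correlates with partner expression only among fusion-positive
    subjects, then tests both strata with Pearson's r. Returns the
    positive-stratum rejection rate (power) and the negative-stratum
    rejection rate at alpha = 0.05 (should sit near the nominal level), plus
    the negative-stratum CI coverage of zero.
    """
    pos_reject = neg_reject = neg_ci_covers_zero = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            seed=seed * 4093 + rep,
            n_subjects=n_subjects,
            n_genes=1,
            n_risk_genes=1,
            fusion_corr=fusion_corr,
            fusion_fraction=0.4,
        )
        panel = simulate_genotype_panel(cfg, cohort=2)
        _, truth = simulate_expression_panel(panel, cfg)
        tumors = simulate_tumor_cohort(panel, truth, cfg)
        reports = stratified_correlation(tumors, boundary=None, method="pearson")
        if reports["positive"].p < 0.05:
            pos_reject += 1
        if reports["negative"].p < 0.05:
            neg_reject += 1
        lo, hi = reports["negative"].ci
        if lo <= 0.0 <= hi:
            neg_ci_covers_zero += 1
    return {
        "n_reps": n_reps,
        "positive_detection_rate": pos_reject / n_reps,
        "negative_type1_rate": neg_reject / n_reps,
        "negative_ci_zero_coverage": neg_ci_covers_zero / n_reps,
    }
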