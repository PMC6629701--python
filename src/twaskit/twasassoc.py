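"""Case-control association of imputed expression, inflation, conditioning,
mediation, replication tiers, and fixed-effects meta-analysis.

The workhorse is a covariate-adjusted logistic regression of disease status
on one gene's imputed expression (maximum likelihood by Newton/IRLS,
convergence tolerance 1e-8, at most 25 iterations). Transcriptome-wide runs
assign Bonferroni tiers (0.05 / n_genes significant, 10x that suggestive) and
report the genomic-control inflation factor lambda_GC together with its
1000-case/1000-control rescaling lambda_1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_CHI2_MEDIAN = 0.4549364  # median of chi-square with 1 df


@dataclass
class AssociationResult:
    gene_id: str
    beta: float
    se: float
    p: float
    tier: str = "null"  # significant | suggestive | null
    converged: bool = True


@dataclass
class InflationStats:
    lambda_gc: float
    lambda_1000: float
    n_cases: int
    n_controls: int


@dataclass
class ConditionalResult:
    gene_id: str
    beta_marginal: float
    beta_conditional: float
    se_conditional: float
    p_conditional: float
    conditioning: list[dict] = field(default_factory=list)


@dataclass
class MediationResult:
    gene_id: str
    mediator_id: str
    proportion_mediated: float  # percent
    ci: tuple[float, float]
    n_boot: int
    flagged: bool = False
    note: str = ""


@dataclass
class MetaResult:
    gene_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    inputs: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# subject filtering


def filter_pc_outliers(
    covariates: pd.DataFrame, k_sd: float = 5.0, n_pcs: int = 2
) -> pd.Index:
    """Retain subjects within ``k_sd`` SD of the mean on the first ``n_pcs`` PCs.

    Means and SDs are computed once on the input set (single pass, not
    iterated). PC columns are ``pc1``, ``pc2``, ...
    """
    idx = np.ones(len(covariates), dtype=bool)
    for j in range(1, n_pcs + 1):
        col = covariates[f"pc{j}"].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise ValueError(f"pc{j} has zero variance")
        idx &= np.abs(col - col.mean()) <= k_sd * sd
    return covariates.index[idx]


# ---------------------------------------------------------------------------
# logistic fitting


def _design(expression, covariates, extra=None, extra_names=()):
    x = [np.asarray(expression, dtype=float)]
    names = ["expression"]
    if covariates is not None:
        for c in covariates.columns:
            x.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != len(x[0]):
            extra = extra.T
        for j in range(extra.shape[1]):
            x.append(extra[:, j])
            names.append(extra_names[j] if j < len(extra_names) else f"cond{j}")
    X = np.column_stack(x)
    return sm.add_constant(X, has_constant="add"), ["const"] + names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    bad = d < max(X.shape) * np.finfo(float).eps * d.max()
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {cols}")


def fit_logistic_association(
    expression,
    status,
    covariates: pd.DataFrame | None = None,
    gene_id: str = "gene",
) -> AssociationResult:
    """Wald test of the expression coefficient in a covariate-adjusted logit.

    Newton (IRLS) maximum likelihood, tolerance 1e-8, at most 25 iterations.
    Separation (diverging coefficients or a non-converged fit) is reported as
    ``converged=False`` with no finite estimate.
    """
    y = np.asarray(status, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X, names = _design(expression, covariates)
    _check_rank(X, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=25, tol=1e-8, disp=0
            )
        except Exception:
            return AssociationResult(
                gene_id, np.nan, np.nan, np.nan, converged=False
            )
    beta = float(res.params[1])
    se = float(res.bse[1])
    diverged = (
        not res.mle_retvals.get("converged", False)
        or abs(beta) > 30
        or not np.isfinite(se)
        or se == 0
    )
    if diverged:
        return AssociationResult(gene_id, np.nan, np.nan, np.nan, converged=False)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssociationResult(gene_id, beta, se, max(p, np.finfo(float).tiny))


def run_twas(
    imputed: pd.DataFrame,
    status,
    covariates: pd.DataFrame | None = None,
) -> tuple[list[AssociationResult], InflationStats, dict]:
    """One logistic fit per gene with Bonferroni tier assignment.

    ``imputed`` is subjects x genes. The significant threshold is
    0.05 / n_genes and the suggestive threshold one order of magnitude
    higher; inflation is computed on the full p-value vector.
    """
    n_genes = imputed.shape[1]
    sig = 0.05 / n_genes
    sugg = 10.0 * sig
    results = []
    for gene_id in imputed.columns:
        r = fit_logistic_association(
            imputed[gene_id].to_numpy(), status, covariates, gene_id=gene_id
        )
        if r.converged and np.isfinite(r.p):
            r.tier = (
                "significant" if r.p < sig else "suggestive" if r.p < sugg else "null"
            )
        results.append(r)
    y = np.asarray(status, dtype=float)
    pvals = np.array([r.p for r in results if r.converged and np.isfinite(r.p)])
    infl = compute_inflation(pvals, int(y.sum()), int((1 - y).sum()))
    return results, infl, {"significant": sig, "suggestive": sugg}


def compute_inflation(p_values, n_cases: int, n_controls: int) -> InflationStats:
    """Genomic-control lambda and its 1000/1000 sample-size rescaling.

    lambda_GC = median(qchisq(p, 1 df, upper)) / 0.4549364;
    lambda_1000 = 1 + (lambda_GC - 1) * (1/n_cases + 1/n_controls) / (2/1000).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / _CHI2_MEDIAN)
    lam_1000 = 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
    return InflationStats(lam, lam_1000, n_cases, n_controls)


# ---------------------------------------------------------------------------
# conditional and mediation analysis


def resolve_conditioning_variants(
    lead_variants,
    panel,
    ld_r2: pd.DataFrame,
    proxy_r2_min: float = 0.8,
    prune_r2: float = 0.2,
) -> tuple[np.ndarray, list[dict]]:
    """Lead-variant dosages with proxy substitution and LD pruning.

    A lead absent from the panel is replaced by its highest-r2 proxy with
    r2 > ``proxy_r2_min`` (ties by smaller distance, then lower position);
    with no proxy it is dropped with a warning. The resolved set is then
    greedily pruned to pairwise r2 < ``prune_r2``.
    """
    used, provenance = [], []
    for lead in lead_variants:
        if lead in panel:
            used.append(lead)
            provenance.append({"lead": lead, "used": lead, "proxy_r2": 1.0})
            continue
        if lead not in ld_r2.index:
            warnings.warn(f"lead variant {lead} has no LD information; dropped")
            continue
        row = ld_r2.loc[lead].drop(labels=[lead], errors="ignore")
        row = row[[v for v in row.index if v in panel]]
        row = row[row > proxy_r2_min]
        if row.empty:
            warnings.warn(f"no proxy above r2 {proxy_r2_min} for {lead}; dropped")
            continue
        best_r2 = row.max()
        cand = list(row.index[row == best_r2])
        if len(cand) > 1 and "position" in panel.variants.columns:
            cand.sort(key=lambda v: int(panel.variants.loc[v, "position"]))
        used.append(cand[0])
        provenance.append({"lead": lead, "used": cand[0], "proxy_r2": float(best_r2)})

    kept, kept_prov = [], []
    for v, prov in zip(used, provenance):
        dos_v = panel.dosage(v)
        ok = True
        for u in kept:
            r = np.corrcoef(dos_v, panel.dosage(u))[0, 1]
            if r**2 >= prune_r2:
                ok = False
                break
        if ok:
            kept.append(v)
            kept_prov.append(prov)
    if not kept:
        raise ValueError("conditioning set is empty after proxy resolution/pruning")
    dosages = np.column_stack([panel.dosage(v) for v in kept])
    return dosages, kept_prov


def conditional_association(
    expression,
    status,
    covariates: pd.DataFrame | None,
    conditioning_dosages: np.ndarray,
    gene_id: str = "gene",
    provenance: list[dict] | None = None,
) -> ConditionalResult:
    """Refit the gene association with conditioning dosages as covariates."""
    marginal = fit_logistic_association(expression, status, covariates, gene_id)
    y = np.asarray(status, dtype=float)
    X, names = _design(expression, covariates, conditioning_dosages)
    _check_rank(X, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(method="newton", maxiter=25, tol=1e-8, disp=0)
    beta_c, se_c = float(res.params[1]), float(res.bse[1])
    p_c = float(2 * stats.norm.sf(abs(beta_c / se_c)))
    return ConditionalResult(
        gene_id=gene_id,
        beta_marginal=marginal.beta,
        beta_conditional=beta_c,
        se_conditional=se_c,
        p_conditional=p_c,
        conditioning=provenance or [],
    )


def mediation_proportion(
    gene_expression,
    mediator_expression,
    status,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    gene_id: str = "gene",
    mediator_id: str = "mediator",
) -> MediationResult:
    """Percent of a gene's marginal log-odds removed by adjusting for a mediator.

    proportion = 100 * (1 - beta_adjusted / beta_marginal), with the adjusted
    beta from the mutually adjusted logistic model. The CI is a seeded
    percentile bootstrap over subjects. A mediator collinear with the gene
    makes the adjusted model indeterminate; the proportion is then capped at
    100 and flagged.
    """
    g = np.asarray(gene_expression, dtype=float)
    m = np.asarray(mediator_expression, dtype=float)
    y = np.asarray(status, dtype=float)

    def _prop(gv, mv, yv, cov):
        try:
            marg = fit_logistic_association(gv, yv, cov)
        except ValueError:  # e.g. near-constant expression -> rank deficiency
            return np.nan, np.nan
        if not marg.converged or abs(marg.beta) < 1e-10:
            return np.nan, marg.beta
        try:
            adj_res = conditional_association(gv, yv, cov, mv.reshape(-1, 1))
        except ValueError:
            return 100.0, marg.beta
        return 100.0 * (1.0 - adj_res.beta_conditional / marg.beta), marg.beta

    point, beta_marg = _prop(g, m, y, covariates)
    if not np.isfinite(point) and not np.isfinite(beta_marg):
        return MediationResult(
            gene_id, mediator_id, np.nan, (np.nan, np.nan), n_boot,
            flagged=True, note="marginal beta undefined",
        )
    if not np.isfinite(point):
        return MediationResult(
            gene_id, mediator_id, np.nan, (np.nan, np.nan), n_boot,
            flagged=True, note="marginal beta below tolerance",
        )

    rng = np.random.default_rng(seed)
    n = len(y)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        cov_b = covariates.iloc[idx].reset_index(drop=True) if covariates is not None else None
        pb, _ = _prop(g[idx], m[idx], y[idx], cov_b)
        if np.isfinite(pb):
            boots.append(pb)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    flagged = not (0.0 <= point <= 100.0) or point == 100.0
    return MediationResult(
        gene_id, mediator_id, float(point), (float(lo), float(hi)), n_boot,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# replication and meta-analysis


def classify_replication(
    discovery: AssociationResult, replication: AssociationResult, n_tested: int
) -> str:
    """Replication tier: Bonferroni (p < 0.05/n_tested), nominal (p < 0.05),
    both requiring a direction of effect consistent with discovery."""
    if discovery.gene_id != replication.gene_id:
        raise ValueError("results are for different genes")
    same_direction = np.sign(discovery.beta) == np.sign(replication.beta)
    if not same_direction or not replication.converged:
        return "not_replicated"
    if replication.p < 0.05 / n_tested:
        return "bonferroni_replicated"
    if replication.p < 0.05:
        return "nominal"
    return "not_replicated"


def fixed_effects_meta(
    inputs: list[tuple[float, float]], gene_id: str = "gene"
) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-stratum (beta, se)."""
    if not inputs:
        raise ValueError("no strata supplied")
    betas = np.array([b for b, _ in inputs], dtype=float)
    ses = np.array([s for _, s in inputs], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MetaResult(gene_id, beta, se, p, inputs=list(inputs))


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "tier": r.tier,
                "converged": r.converged,
            }
            for r in results
        ]
    ).set_index("gene_id")
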