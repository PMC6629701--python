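"""Germline-somatic interaction: imputed normal-tissue expression of a gene
versus observed tumoral expression of its fusion partner, stratified by
fusion status.

A univariate logistic fit of fusion status on partner expression defines a
decision boundary (the expression value at fitted probability 0.5); samples
on the wrong side of the boundary for their recorded status are excluded as
likely misclassified. Within each stratum, the imputed-observed relationship
is summarized by Pearson's r (regression slope p, Fisher-z CI, Shapiro-Wilk
residual normality) or Spearman's rho with a seeded percentile bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .twasassoc import AssociationResult, fit_logistic_association


@dataclass
class DecisionBoundary:
    """Exclusion rule: positives below the threshold and negatives above it
    are treated as misclassified."""

    threshold: float
    separated: bool = False

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass
class CorrelationReport:
    method: str  # pearson | spearman
    estimate: float
    ci: tuple[float, float]
    p: float
    n: int
    residual_normality_p: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    flagged: bool = False


def fit_fusion_decision_boundary(
    partner_expression, fusion_positive
) -> DecisionBoundary:
    """Fit fusion status on partner expression; threshold = -b0/b1.

    Raises when only one status is present or when expression does not
    discriminate status (non-positive slope). Perfect separation leaves the
    threshold in the separating gap and flags the boundary.
    """
    x = np.asarray(partner_expression, dtype=float)
    y = np.asarray(fusion_positive, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both fusion statuses must be present")
    if x[y == 1].min() > x[y == 0].max():
        # perfect separation: the MLE diverges and any threshold in the gap
        # classifies perfectly; report the gap midpoint, flagged
        return DecisionBoundary(
            0.5 * (x[y == 1].min() + x[y == 0].max()), separated=True
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, sm.add_constant(x)).fit(
            method="newton", maxiter=100, tol=1e-8, disp=0
        )
        b0, b1 = res.params
        se1 = float(res.bse[1])
    # the slope must be credibly positive: identical or negatively-ordered
    # groups have no meaningful 0.5-probability crossing
    if b1 <= 0 or not np.isfinite(se1) or b1 / se1 < 2.0:
        raise ValueError("expression does not discriminate status")
    threshold = float(-b0 / b1)
    if not (x.min() <= threshold <= x.max()):
        raise ValueError("expression does not discriminate status")
    return DecisionBoundary(threshold)


def apply_fusion_decision_boundary(
    samples: pd.DataFrame, boundary: DecisionBoundary
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tumor samples into retained and excluded sets.

    ``samples`` needs columns ``partner_rpkm`` and ``fusion_status``
    ('positive'/'negative'). Positives with expression strictly below the
    threshold and negatives strictly above it are excluded, each with a
    reason.
    """
    rpkm = samples["partner_rpkm"].to_numpy(dtype=float)
    pos = samples["fusion_status"].astype(str).str.lower().eq("positive").to_numpy()
    drop_pos = pos & (rpkm < boundary.threshold)
    drop_neg = ~pos & (rpkm > boundary.threshold)
    excluded = samples[drop_pos | drop_neg].copy()
    excluded["exclusion_reason"] = np.where(
        drop_pos[drop_pos | drop_neg],
        f"positive below {boundary.threshold:g}",
        f"negative above {boundary.threshold:g}",
    )
    return samples[~(drop_pos | drop_neg)].copy(), excluded


def correlate_imputed_observed(
    x,
    y,
    method: str = "pearson",
    n_boot: int = 10_000,
    seed: int = 0,
) -> CorrelationReport:
    """Correlation between imputed and observed expression.

    Pearson: least-squares slope test p, Fisher-z 95% CI, Shapiro-Wilk on the
    regression residuals. Spearman: rank correlation with a seeded percentile
    bootstrap CI over subject pairs (``n_boot`` resamples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationReport(method, np.nan, (np.nan, np.nan), np.nan, n, flagged=True)

    if method == "pearson":
        lr = stats.linregress(x, y)
        r = float(lr.rvalue)
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        hw = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
        resid = y - (lr.intercept + lr.slope * x)
        if np.ptp(resid) < 1e-12 * (1 + np.ptp(y)):
            sw_p = 1.0  # exact fit: residuals carry no information
        else:
            sw_p = float(stats.shapiro(resid)[1])
        return CorrelationReport(
            "pearson", r, ci, float(lr.pvalue), n, residual_normality_p=sw_p
        )
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.std(x[idx]) == 0 or np.std(y[idx]) == 0:
                continue
            boots.append(stats.spearmanr(x[idx], y[idx])[0])
        lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
        return CorrelationReport(
            "spearman", float(rho), (float(lo), float(hi)), float(p), n,
            n_boot=n_boot, seed=seed,
        )
    raise ValueError(f"unknown method {method!r}")


def stratified_correlation(
    samples: pd.DataFrame,
    boundary: DecisionBoundary | None = None,
    method: str = "pearson",
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, CorrelationReport]:
    """Boundary exclusion followed by per-stratum imputed/observed correlation.

    ``samples`` needs ``imputed_expression``, ``partner_rpkm`` and
    ``fusion_status``. Returns reports keyed 'positive'/'negative'.
    """
    if boundary is not None:
        samples, _ = apply_fusion_decision_boundary(samples, boundary)
    out = {}
    for label in ("positive", "negative"):
        sub = samples[samples["fusion_status"].astype(str).str.lower() == label]
        out[label] = correlate_imputed_observed(
            sub["imputed_expression"].to_numpy(),
            sub["partner_rpkm"].to_numpy(),
            method=method,
            n_boot=n_boot,
            seed=seed,
        )
    return out


def test_subtype_association(
    imputed, subtype_labels, gene_id: str = "gene"
) -> AssociationResult:
    """Logistic one-vs-rest association of imputed expression with a tumor
    subtype label (delegates to the TWAS logistic contract)."""
    return fit_logistic_association(imputed, subtype_labels, None, gene_id=gene_id)
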