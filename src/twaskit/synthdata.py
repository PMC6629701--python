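"""Synthetic cohorts with the statistical structure a prostate-tissue TWAS assumes.

The generator produces, from a single :class:`SimulationConfig`:

* an LD-structured diploid genotype panel (block copula haplotypes),
* a training expression matrix with a sparse cis-eQTL architecture at a
  configurable narrow-sense heritability,
* a case-control cohort whose disease log-odds are mediated by the genetic
  component of expression at designated risk genes, with age/BMI/PC
  confounders,
* a tumor cohort with binary fusion status in which the fusion-partner's
  tumoral expression tracks the germline genetic score only in
  fusion-positive subjects, and
* TFBS/peak/binding-affinity annotations with configurable enrichment and
  allele-direction concordance.

Every draw flows from one seed; per-stage generators are derived
deterministically, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .panel import GenotypePanel

# stage offsets for deterministic sub-streams
_STAGE_GENO = 1
_STAGE_EXPR = 2
_STAGE_COHORT = 3
_STAGE_TUMOR = 4
_STAGE_REGANN = 5


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale study: 500 training subjects, 200 genes
    with 10 cis variants each (3 causal), expression heritability 0.5, and
    10 risk genes at log-OR 0.4 per SD of genetic expression. Cases and
    controls are drawn from a balanced base population (prevalence 0.5),
    mirroring a case-control rather than cohort sampling design.
    """

    seed: int = 0
    n_subjects: int = 500
    n_variants_per_gene: int = 10
    n_genes: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    n_causal_eqtls_per_gene: int = 3
    expression_h2: float = 0.5
    n_risk_genes: int = 10
    risk_log_or_per_sd: float = 0.4
    disease_prevalence: float = 0.5
    covariate_effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    fusion_fraction: float = 0.4
    fusion_erg_shift: float = 15.0
    fusion_corr: float = 0.3
    tfbs_enrichment_or: float = 5.0
    binding_concordance: float = 0.8
    ld_corr: float = 0.8  # within-block haplotype copula correlation

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_variants_per_gene, self.n_genes) <= 0:
            raise ConfigurationError("dimensions must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie strictly inside (0, 0.5]")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not 0.0 <= self.expression_h2 <= 1.0:
            raise ConfigurationError("expression_h2 must be in [0, 1]")
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ConfigurationError("disease_prevalence must be in (0, 1)")
        if not 0.0 <= self.fusion_fraction <= 1.0:
            raise ConfigurationError("fusion_fraction must be in [0, 1]")
        if self.tfbs_enrichment_or < 0:
            raise ConfigurationError("tfbs_enrichment_or must be >= 0")
        if self.n_causal_eqtls_per_gene > self.n_variants_per_gene:
            raise ConfigurationError("more causal eQTLs than variants per gene")
        if self.n_risk_genes > self.n_genes:
            raise ConfigurationError("more risk genes than genes")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class TruthTable:
    """Ground truth underlying one simulated study.

    ``eqtls`` maps gene -> DataFrame(variant_id, weight) of causal variants on
    the raw dosage scale; ``risk`` maps risk gene -> log-OR per SD of its
    genetic expression score; ``fusion_status`` is filled by
    :func:`simulate_tumor_cohort`.
    """

    eqtls: dict[str, pd.DataFrame]
    risk: dict[str, float]
    fusion_status: np.ndarray | None = None

    def genetic_score(self, panel: GenotypePanel, gene_id: str) -> np.ndarray:
        """Raw genetic expression value: dosage-weighted sum of causal eQTLs."""
        tab = self.eqtls[gene_id]
        score = np.zeros(panel.n_subjects)
        for vid, w in zip(tab["variant_id"], tab["weight"]):
            score += w * panel.dosage(vid)
        return score

    def to_tsv(self, path) -> None:
        rows = []
        for g, tab in self.eqtls.items():
            for vid, w in zip(tab["variant_id"], tab["weight"]):
                rows.append((g, vid, w, self.risk.get(g, 0.0)))
        pd.DataFrame(
            rows, columns=["gene_id", "variant_id", "weight", "risk_log_or"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome layout


def gene_annotations(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene map: genes round-robin across 22 autosomes, 2 Mb apart."""
    rows = []
    for g in range(config.n_genes):
        chrom = str(g % 22 + 1)
        start = 1_000_000 + (g // 22) * 2_000_000
        rows.append((f"G{g:04d}", chrom, start, start + 10_000, "+"))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    ).set_index("gene_id")


def variants_for_gene(config: SimulationConfig, gene_id: str) -> list[str]:
    g = int(gene_id[1:])
    return [f"G{g:04d}_v{k:03d}" for k in range(config.n_variants_per_gene)]


# ---------------------------------------------------------------------------
# generators


def simulate_genotype_panel(config: SimulationConfig, cohort: int = 0) -> GenotypePanel:
    """LD-structured diploid dosages.

    Haplotype alleles come from a Gaussian block copula: within a block of
    ``ld_block_size`` consecutive variants the latent normals share a common
    factor with loading sqrt(ld_corr); across blocks (and genes) variants are
    independent. Per-variant MAF is uniform on ``maf_range`` and the alt
    allele is the minor allele.

    Variant properties (positions, MAFs) depend only on the config seed, so
    panels generated with different ``cohort`` numbers describe independent
    subject draws from the same population: use cohort 0 for the training
    panel, 1 for a discovery cohort, 2 for a tumor cohort, and so on.
    """
    prop_rng = config.rng(_STAGE_GENO)
    rng = np.random.default_rng([int(config.seed), _STAGE_GENO, 1000 + int(cohort)])
    genes = gene_annotations(config)
    n, v = config.n_subjects, config.n_variants_per_gene
    rho = config.ld_corr if config.ld_block_size > 1 else 0.0

    meta_rows = []
    blocks = []
    for gene_id, ann in genes.iterrows():
        mafs = prop_rng.uniform(*config.maf_range, size=v)
        lo = ann.start - 250_000
        hi = ann.end + 250_000
        positions = np.sort(prop_rng.choice(np.arange(lo, hi), size=v, replace=False))
        thresh = stats.norm.ppf(mafs)
        n_blocks = -(-v // config.ld_block_size)
        dose = np.zeros((n, v), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, n_blocks))
            shared = np.repeat(shared, config.ld_block_size, axis=1)[:, :v]
            z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, v))
            dose += (z < thresh).astype(np.int8)
        blocks.append(dose)
        for k in range(v):
            ref, alt = ("A", "G") if k % 2 == 0 else ("C", "T")
            meta_rows.append(
                (
                    f"{gene_id}_v{k:03d}",
                    ann.chromosome,
                    int(positions[k]),
                    ref,
                    alt,
                    1.0,
                )
            )
    variants = pd.DataFrame(
        meta_rows,
        columns=["variant_id", "chromosome", "position", "ref", "alt", "info_r2"],
    ).set_index("variant_id")
    return GenotypePanel(
        variants=variants, dosages=np.concatenate(blocks, axis=1)
    )


def simulate_expression_panel(
    panel: GenotypePanel, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthTable]:
    """Expression = genetic value + noise, variance-partitioned at ``expression_h2``.

    Per gene, ``n_causal_eqtls_per_gene`` variants get N(0,1) raw weights; the
    genetic value is standardized in-panel and mixed with independent Gaussian
    noise as sqrt(h2) * z_genetic + sqrt(1 - h2) * eps, so the genetic
    variance fraction equals ``expression_h2`` exactly in expectation (and the
    h2 = 1 / h2 = 0 edges are exact).

    Returns an expression DataFrame (genes x subjects) and the ground truth.
    """
    rng = config.rng(_STAGE_EXPR)
    h2 = config.expression_h2
    genes = gene_annotations(config)
    eqtls: dict[str, pd.DataFrame] = {}
    expr = np.zeros((config.n_genes, panel.n_subjects))
    for i, gene_id in enumerate(genes.index):
        vids = variants_for_gene(config, gene_id)
        causal = sorted(
            rng.choice(len(vids), size=config.n_causal_eqtls_per_gene, replace=False)
        )
        weights = rng.standard_normal(len(causal))
        tab = pd.DataFrame(
            {"variant_id": [vids[c] for c in causal], "weight": weights}
        )
        eqtls[gene_id] = tab
        score = np.zeros(panel.n_subjects)
        for vid, w in zip(tab["variant_id"], tab["weight"]):
            score += w * panel.dosage(vid)
        sd = score.std()
        z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
        noise = rng.standard_normal(panel.n_subjects)
        expr[i] = np.sqrt(h2) * z + np.sqrt(1.0 - h2) * noise

    risk_idx = rng.choice(config.n_genes, size=config.n_risk_genes, replace=False)
    risk = {genes.index[i]: config.risk_log_or_per_sd for i in sorted(risk_idx)}
    truth = TruthTable(eqtls=eqtls, risk=risk)
    expr_df = pd.DataFrame(expr, index=genes.index, columns=panel.subjects)
    return expr_df, truth


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept making mean case probability = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_case_control_cohort(
    panel: GenotypePanel,
    truth: TruthTable,
    config: SimulationConfig,
    draw: int = 0,
) -> pd.DataFrame:
    """Binary disease status from a logistic model on genetic expression scores.

    logit P(case) = intercept(prevalence) + sum over risk genes of
    log-OR x standardized genetic score + covariate effects. Covariates are
    two standard-normal PCs, an age-like N(60, 8) (age at diagnosis for cases
    is not distinguished at generation time) and a BMI-like N(27, 4);
    configured effects apply to their standardized values.

    Returns a DataFrame aligned with ``panel.subjects`` holding ``status``,
    ``age``, ``bmi``, ``pc1``, ``pc2``.
    """
    missing = [g for g in truth.risk if g not in truth.eqtls]
    if missing:
        raise ConfigurationError(f"risk genes absent from truth table: {missing}")
    rng = np.random.default_rng([int(config.seed), _STAGE_COHORT, int(draw)])
    n = panel.n_subjects
    pc1, pc2 = rng.standard_normal(n), rng.standard_normal(n)
    age = rng.normal(60.0, 8.0, size=n)
    bmi = rng.normal(27.0, 4.0, size=n)

    eta = np.zeros(n)
    for gene_id, lor in truth.risk.items():
        score = truth.genetic_score(panel, gene_id)
        sd = score.std()
        if sd > 0:
            eta += lor * (score - score.mean()) / sd
    zcov = np.column_stack([pc1, pc2, (age - 60.0) / 8.0, (bmi - 27.0) / 4.0])
    eta += zcov @ np.asarray(config.covariate_effects, dtype=float)

    intercept = _solve_intercept(eta, config.disease_prevalence)
    status = rng.random(n) < expit(intercept + eta)
    return pd.DataFrame(
        {
            "status": status.astype(int),
            "age": age,
            "bmi": bmi,
            "pc1": pc1,
            "pc2": pc2,
        },
        index=panel.subjects,
    )


def sample_case_control(
    phenotypes: pd.DataFrame, n_cases: int, n_controls: int, seed: int
) -> np.ndarray:
    """Row positions of a case-control draw from a simulated population."""
    rng = np.random.default_rng(seed)
    status = phenotypes["status"].to_numpy()
    cases = np.flatnonzero(status == 1)
    controls = np.flatnonzero(status == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ConfigurationError(
            f"population has {len(cases)} cases / {len(controls)} controls; "
            f"requested {n_cases}/{n_controls}"
        )
    pick = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    return np.sort(pick)


def simulate_tumor_cohort(
    panel: GenotypePanel,
    truth: TruthTable,
    config: SimulationConfig,
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Tumor cohort with fusion status and fusion-partner tumoral expression.

    In fusion-positive subjects the partner RPKM is
    baseline + fusion_erg_shift + 2 * (fusion_corr * z + sqrt(1-corr^2) * eps),
    where z is the standardized germline genetic score of ``gene_id``
    (default: the first risk gene), so the within-positives Pearson
    correlation with the genetic score equals ``fusion_corr``. In
    fusion-negative subjects expression is independent of the genetic score.
    RPKM is floored at 0.
    """
    rng = config.rng(_STAGE_TUMOR)
    if gene_id is None:
        gene_id = next(iter(truth.risk), next(iter(truth.eqtls)))
    score = truth.genetic_score(panel, gene_id)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)

    n = panel.n_subjects
    fusion = rng.random(n) < config.fusion_fraction
    baseline = 3.0
    c = config.fusion_corr
    eps = rng.standard_normal(n)
    rpkm = np.where(
        fusion,
        baseline
        + config.fusion_erg_shift
        + 2.0 * (c * z + np.sqrt(max(0.0, 1.0 - c**2)) * eps),
        baseline + 2.0 * eps,
    )
    truth.fusion_status = fusion.astype(int)
    return pd.DataFrame(
        {
            "subject_id": panel.subjects,
            "gene_id": gene_id,
            "imputed_expression": z,
            "partner_rpkm": np.maximum(rpkm, 0.0),
            "fusion_status": np.where(fusion, "positive", "negative"),
        }
    )


def simulate_regulatory_annotations(
    model_db,
    config: SimulationConfig,
    genes_of_interest: list[str] | None = None,
    n_background: int = 100,
    background_cat1_prob: float = 0.3,
):
    """TFBS annotations, H3K27ac-like peaks and binding-affinity profiles.

    Genes of interest receive category-1 evidence (prostate-line ChIP-Seq)
    with odds ``tfbs_enrichment_or`` times the background odds
    (``background_cat1_prob``, default 0.3). Binding-affinity profiles for
    evidence-bearing variants favor the expression-increasing allele with
    probability ``binding_concordance``.

    Returns ``(annotations, peaks, profiles, genes_of_interest, background)``
    where ``annotations`` is a DataFrame (gene_id, variant_id, source,
    factor), ``peaks`` a :class:`~twaskit.regmech.PeakSet`, and ``profiles``
    a list of :class:`~twaskit.regmech.BindingAffinityProfile`.
    """
    from .regmech import BindingAffinityProfile, PeakSet

    if len(model_db) == 0:
        raise ConfigurationError("model database is empty")
    rng = config.rng(_STAGE_REGANN)
    genes = list(model_db.genes())
    if genes_of_interest is None:
        genes_of_interest = genes[: min(19, len(genes))]
    pool = [g for g in genes if g not in set(genes_of_interest)]
    n_background = min(n_background, len(pool))
    background = list(rng.choice(pool, size=n_background, replace=False))

    p0 = background_cat1_prob
    odds1 = config.tfbs_enrichment_or * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)

    ann_rows = []
    profiles = []
    intervals = []
    for gene_id in genes_of_interest + background:
        model = model_db[gene_id]
        vids = sorted(model.weights)
        prob = p1 if gene_id in set(genes_of_interest) else p0
        if rng.random() < prob:
            vid = vids[int(rng.integers(len(vids)))]
            ann_rows.append((gene_id, vid, "chipseq_prostate", "AR"))
            w = model.weights[vid][2]
            concordant = rng.random() < config.binding_concordance
            # negative score (stronger A1 binding) should pair with positive
            # expression weight when concordant
            sign = -1.0 if (w > 0) == concordant else 1.0
            mats = []
            for m in range(6):
                delta = sign * abs(rng.normal(1.0, 0.2))
                base = -2.0 - rng.random()
                mats.append((f"V$AR_{m:02d}", m + 1, base + delta / 2, base - delta / 2))
            profiles.append(
                BindingAffinityProfile(
                    variant_id=vid,
                    allele1=model.weights[vid][0],
                    allele2=model.weights[vid][1],
                    matrices=mats,
                )
            )
            # enhancer-mark peaks over the evidence variant in several samples
            pos = None
            if model.variant_positions and vid in model.variant_positions:
                chrom, pos = model.variant_positions[vid]
            if pos is not None:
                for s in range(int(rng.integers(4, 12))):
                    pad = int(rng.integers(200, 2_000))
                    intervals.append(
                        (chrom, max(0, pos - 1 - pad), pos + pad, f"tumor{s:02d}")
                    )
        elif rng.random() < 0.5:
            vid = vids[int(rng.integers(len(vids)))]
            src = ["dnase_prostate", "chipseq_other", "motif_pwm"][
                int(rng.integers(3))
            ]
            ann_rows.append((gene_id, vid, src, "CTCF"))

    annotations = pd.DataFrame(
        ann_rows, columns=["gene_id", "variant_id", "source", "factor"]
    )
    peaks = PeakSet.from_records(intervals)
    return annotations, peaks, profiles, list(genes_of_interest), background
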