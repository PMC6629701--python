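"""Per-gene cis-regulatory expression models.

Each gene's expression is regressed on the dosages of well-imputed variants
within a symmetric cis window (default +/- 500 kb of the gene boundaries,
inclusive) with an elastic net (mixing parameter alpha = 0.5). The penalty is
chosen to minimize cross-validated squared error (leave-one-out by default,
k-fold available), and genes whose selected fit keeps no non-intercept
coefficient are not emitted. Weights are reported on the raw dosage scale so
they can be applied directly to cohort dosages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, LeaveOneOut, cross_val_predict

from .panel import GenotypePanel


@dataclass
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class TrainingConfig:
    """Knobs of the elastic-net training procedure.

    ``info_r2_min`` is a strict lower bound: variants must exceed it to enter
    the candidate set.
    """

    cis_window_bp: int = 500_000
    mixing_alpha: float = 0.5
    info_r2_min: float = 0.8
    cv_scheme: str = "loo"  # "loo" | "kfold"
    n_folds: int = 10
    n_lambdas: int = 100
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")
        if not 0.0 <= self.mixing_alpha <= 1.0:
            raise ValueError("mixing_alpha must be in [0, 1]")
        if self.cv_scheme not in ("loo", "kfold"):
            raise ValueError("cv_scheme must be 'loo' or 'kfold'")

    def splitter(self, n: int):
        if self.cv_scheme == "loo":
            return LeaveOneOut()
        return KFold(
            n_splits=min(self.n_folds, n), shuffle=True, random_state=self.seed
        )


@dataclass
class ExpressionModel:
    """Sparse eQTL weight set for one gene.

    ``weights`` maps variant_id -> (effect_allele, other_allele, weight);
    weights are per effect-allele dosage on the raw scale. ``cv_r2`` is the
    squared Pearson correlation between cross-validated predictions and
    observed expression at the selected penalty.
    """

    gene_id: str
    intercept: float
    weights: dict[str, tuple[str, str, float]]
    cv_r2: float
    n_variants: int
    variant_positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_variants != len(self.weights):
            raise ValueError("n_variants must equal the number of nonzero weights")
        if self.n_variants < 1:
            raise ValueError("a model must keep at least one non-intercept weight")


class ModelDatabase:
    """Collection of :class:`ExpressionModel` keyed by gene, with provenance."""

    def __init__(self, models=None, metadata: dict | None = None):
        self._models: dict[str, ExpressionModel] = {}
        for m in models or []:
            self.add(m)
        self.metadata = dict(metadata or {})

    def add(self, model: ExpressionModel) -> None:
        if model.gene_id in self._models:
            raise ValueError(f"duplicate gene_id {model.gene_id}")
        self._models[model.gene_id] = model

    def genes(self):
        return self._models.keys()

    def __len__(self) -> int:
        return len(self._models)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __getitem__(self, gene_id: str) -> ExpressionModel:
        return self._models[gene_id]

    def __iter__(self):
        return iter(self._models.values())

    # -- persistence: weights TSV + JSON sidecar ----------------------------

    def to_files(self, weights_path, sidecar_path) -> None:
        rows = []
        side = {"metadata": self.metadata, "genes": {}}
        for m in self:
            for vid, (ea, oa, w) in sorted(m.weights.items()):
                chrom, pos = m.variant_positions.get(vid, ("", -1))
                rows.append((m.gene_id, vid, chrom, pos, ea, oa, w))
            side["genes"][m.gene_id] = {
                "intercept": m.intercept,
                "cv_r2": m.cv_r2,
                "n_variants": m.n_variants,
            }
        pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "variant_id",
                "chromosome",
                "position",
                "effect_allele",
                "other_allele",
                "weight",
            ],
        ).to_csv(weights_path, sep="\t", index=False)
        with open(sidecar_path, "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def from_files(cls, weights_path, sidecar_path) -> "ModelDatabase":
        tab = pd.read_csv(weights_path, sep="\t", dtype={"chromosome": str})
        with open(sidecar_path) as fh:
            side = json.load(fh)
        db = cls(metadata=side.get("metadata", {}))
        for gene_id, sub in tab.groupby("gene_id", sort=True):
            info = side["genes"][gene_id]
            weights = {
                r.variant_id: (r.effect_allele, r.other_allele, float(r.weight))
                for r in sub.itertuples()
            }
            positions = {
                r.variant_id: (str(r.chromosome), int(r.position))
                for r in sub.itertuples()
                if r.position >= 0
            }
            db.add(
                ExpressionModel(
                    gene_id=gene_id,
                    intercept=float(info["intercept"]),
                    weights=weights,
                    cv_r2=float(info["cv_r2"]),
                    n_variants=int(info["n_variants"]),
                    variant_positions=positions,
                )
            )
        return db


@dataclass
class ModelEvaluation:
    """Out-of-sample evaluation of a model set on one observed panel."""

    per_gene: pd.DataFrame  # index gene_id; columns mse, rho, flagged
    mean_mse: float
    mean_rho: float


# ---------------------------------------------------------------------------
# operations


def extract_cis_window(
    gene: GeneAnnotation, panel: GenotypePanel, config: TrainingConfig
) -> list[str]:
    """Candidate variant ids: same chromosome, position within
    [start - window, end + window] (inclusive at both bounds), INFO r2 above
    the threshold."""
    v = panel.variants
    lo = gene.start - config.cis_window_bp
    hi = gene.end + config.cis_window_bp
    mask = (
        (v["chromosome"].astype(str) == str(gene.chromosome))
        & (v["position"] >= lo)
        & (v["position"] <= hi)
        & (v["info_r2"] > config.info_r2_min)
    )
    return list(v.index[mask])


def fit_expression_model(
    dosages: np.ndarray,
    expression: np.ndarray,
    variant_meta: pd.DataFrame,
    config: TrainingConfig,
    gene_id: str = "gene",
) -> ExpressionModel | None:
    """Elastic-net fit of one gene's expression on its cis dosages.

    Predictors are standardized internally; the penalty minimizing mean
    cross-validated squared error is selected (ties broken toward the
    smallest penalty), and coefficients are reported back on the raw dosage
    scale. Returns None when expression is constant or every non-intercept
    coefficient shrinks to zero at the selected penalty.

    ``variant_meta`` must be indexed by variant_id (column order matching
    ``dosages``) with columns ``ref``, ``alt`` and optionally
    ``chromosome``/``position``; the alt allele is the effect allele.
    """
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("dosage rows and expression length disagree")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(y) == 0:
        return None  # zero variance outcome

    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size == 0:
        return None
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    n = X.shape[0]
    cv = config.splitter(n)
    l1 = max(config.mixing_alpha, 1e-3)  # sklearn path needs l1_ratio > 0
    search = ElasticNetCV(
        l1_ratio=l1,
        alphas=config.n_lambdas,  # size of the automatic log-spaced grid
        cv=cv,
        tol=config.tol,
        max_iter=10_000,
    )
    search.fit(Xs, y)
    mean_mse = search.mse_path_.mean(axis=-1)
    best = np.min(mean_mse)
    # alphas_ are descending; the last minimizer is the smallest penalty
    idx = int(np.max(np.flatnonzero(mean_mse == best)))
    lam = float(search.alphas_[idx])

    model = ElasticNet(alpha=lam, l1_ratio=l1, tol=config.tol, max_iter=10_000)
    model.fit(Xs, y)
    nz = np.flatnonzero(model.coef_ != 0)
    if nz.size == 0:
        return None

    cv_pred = cross_val_predict(
        ElasticNet(alpha=lam, l1_ratio=l1, tol=config.tol, max_iter=10_000),
        Xs,
        y,
        cv=config.splitter(n),
    )
    if np.std(cv_pred) == 0:
        cv_r2 = 0.0
    else:
        cv_r2 = float(stats.pearsonr(cv_pred, y)[0] ** 2)

    # back-transform to the raw dosage scale
    w_raw = model.coef_[nz] / sd[keep][nz]
    cols = keep[nz]
    intercept = float(
        model.intercept_ - np.sum(w_raw * X[:, cols].mean(axis=0))
    )
    weights, positions = {}, {}
    for c, w in zip(cols, w_raw):
        row = variant_meta.iloc[c]
        vid = variant_meta.index[c]
        weights[vid] = (str(row["alt"]), str(row["ref"]), float(w))
        if "position" in variant_meta.columns:
            positions[vid] = (str(row.get("chromosome", "")), int(row["position"]))
    return ExpressionModel(
        gene_id=gene_id,
        intercept=intercept,
        weights=weights,
        cv_r2=cv_r2,
        n_variants=len(weights),
        variant_positions=positions,
    )


def train_model_database(
    panel: GenotypePanel,
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    config: TrainingConfig | None = None,
) -> tuple[ModelDatabase, pd.DataFrame]:
    """Train models for every gene; returns the database and a skip log.

    ``expression`` is genes x subjects (columns aligned with
    ``panel.subjects``); ``genes`` is indexed by gene_id with columns
    chromosome/start/end[/strand].
    """
    config = config or TrainingConfig()
    db = ModelDatabase(
        metadata={
            "cis_window_bp": config.cis_window_bp,
            "mixing_alpha": config.mixing_alpha,
            "info_r2_min": config.info_r2_min,
            "cv_scheme": config.cv_scheme,
            "seed": config.seed,
        }
    )
    skipped = []
    for gene_id, ann in genes.iterrows():
        if gene_id not in expression.index:
            skipped.append((gene_id, "no expression"))
            continue
        gene = GeneAnnotation(
            gene_id, str(ann["chromosome"]), int(ann["start"]), int(ann["end"])
        )
        cand = extract_cis_window(gene, panel, config)
        if not cand:
            skipped.append((gene_id, "no cis variants"))
            continue
        sub = panel.subset(cand)
        m = fit_expression_model(
            np.asarray(sub.dosages, dtype=float),
            expression.loc[gene_id].to_numpy(dtype=float),
            sub.variants,
            config,
            gene_id=gene_id,
        )
        if m is None:
            skipped.append((gene_id, "null fit"))
        else:
            db.add(m)
    return db, pd.DataFrame(skipped, columns=["gene_id", "reason"])


def evaluate_out_of_sample(
    model_db: ModelDatabase, panel: GenotypePanel, observed: pd.DataFrame
) -> ModelEvaluation:
    """Standardized out-of-sample MSE and Spearman rho per gene.

    Observed and imputed vectors are z-standardized per gene before the MSE;
    genes whose prediction is constant are flagged and excluded from the
    means (rank correlation is undefined there).
    """
    from .imputex import impute_gene_expression

    genes = [g for g in model_db.genes() if g in observed.index]
    if not genes:
        raise ValueError("no overlapping genes between models and observed panel")
    rows = []
    for g in genes:
        pred, _ = impute_gene_expression(model_db[g], panel)
        obs = observed.loc[g].to_numpy(dtype=float)
        if len(obs) < 3:
            raise ValueError("need at least 3 overlapping subjects")
        # constant up to summation rounding counts as constant
        if np.std(pred) <= 1e-12 * (1 + abs(pred.mean())) or np.std(obs) == 0:
            rows.append((g, np.nan, np.nan, True))
            continue
        zp = (pred - pred.mean()) / pred.std()
        zo = (obs - obs.mean()) / obs.std()
        mse = float(np.mean((zp - zo) ** 2))
        rho = float(stats.spearmanr(zp, zo)[0])
        rows.append((g, mse, rho, False))
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "mse", "rho", "flagged"]
    ).set_index("gene_id")
    ok = per_gene[~per_gene["flagged"]]
    return ModelEvaluation(
        per_gene=per_gene,
        mean_mse=float(ok["mse"].mean()),
        mean_rho=float(ok["rho"].mean()),
    )


def compare_model_sets(eval_a: ModelEvaluation, eval_b: ModelEvaluation) -> dict:
    """Paired two-sided t-tests on per-gene rho and MSE differences (a - b)."""
    common = eval_a.per_gene.index.intersection(eval_b.per_gene.index)
    a = eval_a.per_gene.loc[common]
    b = eval_b.per_gene.loc[common]
    ok = ~(a["flagged"] | b["flagged"])
    if ok.sum() == 0:
        raise ValueError("gene intersection is empty after flag filtering")
    out = {"n_genes": int(ok.sum())}
    for metric in ("rho", "mse"):
        d = (a.loc[ok, metric] - b.loc[ok, metric]).to_numpy()
        entry = {
            "mean_a": float(a.loc[ok, metric].mean()),
            "mean_b": float(b.loc[ok, metric].mean()),
            "mean_diff": float(d.mean()),
            "degenerate": bool(np.allclose(d, 0)),
        }
        if entry["degenerate"]:
            entry["p"] = 1.0
        else:
            entry["p"] = float(stats.ttest_rel(a.loc[ok, metric], b.loc[ok, metric])[1])
        out[metric] = entry
    return out
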