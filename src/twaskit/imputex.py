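"""Allele-harmonized imputation of genetically regulated expression.

Model weights are stated per effect-allele dosage; a target cohort codes each
variant by its own ref/alt (and possibly the opposite strand). Harmonization
reconciles the two codings: direct match, ref/alt swap (dosage becomes
2 - d), strand flip (reverse complement), or both. Strand-ambiguous pairs
(A/T, C/G) and indels are dropped; modeled variants absent from the cohort
are omitted from the prediction (equivalent to an effect-allele dosage of
zero), so predictions remain an affine function of the available dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cistrain import ExpressionModel, ModelDatabase
from .panel import GenotypePanel

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizationResult:
    """Outcome of matching one model variant against a cohort coding.

    ``status`` is one of direct, swapped, strand_flipped,
    strand_flipped_swapped, ambiguous_dropped, indel_dropped, missing.
    ``swap_dosage`` is True when the effect-allele dosage is 2 - d.
    """

    status: str
    swap_dosage: bool = False

    @property
    def usable(self) -> bool:
        return self.status in (
            "direct",
            "swapped",
            "strand_flipped",
            "strand_flipped_swapped",
        )


def _is_indel(allele: str) -> bool:
    return len(allele) != 1 or allele.upper() not in _COMPLEMENT


def harmonize_variant(
    effect_allele: str,
    other_allele: str,
    ref_allele: str | None,
    alt_allele: str | None,
) -> HarmonizationResult:
    """Match model (effect, other) alleles to a cohort (ref, alt) coding.

    Pass ``ref_allele=None`` for a variant absent from the cohort. Checks are
    ordered: indels, strand-ambiguous model pairs, then direct / swapped /
    strand-flipped / strand-flipped-swapped; anything irreconcilable is
    ``missing``.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    if _is_indel(ea) or _is_indel(oa):
        return HarmonizationResult("indel_dropped")
    if {ea, oa} in _AMBIGUOUS:
        return HarmonizationResult("ambiguous_dropped")
    if ref_allele is None or alt_allele is None:
        return HarmonizationResult("missing")
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if _is_indel(ref) or _is_indel(alt):
        return HarmonizationResult("indel_dropped")
    if (ea, oa) == (alt, ref):
        return HarmonizationResult("direct")
    if (ea, oa) == (ref, alt):
        return HarmonizationResult("swapped", swap_dosage=True)
    fea, foa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (fea, foa) == (alt, ref):
        return HarmonizationResult("strand_flipped")
    if (fea, foa) == (ref, alt):
        return HarmonizationResult("strand_flipped_swapped", swap_dosage=True)
    return HarmonizationResult("missing")


def impute_gene_expression(
    model: ExpressionModel, panel: GenotypePanel
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted expression for one gene plus a per-variant harmonization report.

    prediction = intercept + sum over found variants of
    weight x effect-allele dosage; dropped or missing variants contribute
    nothing. Raises ValueError when every modeled variant is unusable.
    """
    pred = np.full(panel.n_subjects, model.intercept, dtype=float)
    report = []
    n_found = 0
    for vid, (ea, oa, w) in model.weights.items():
        if vid in panel:
            rec = panel.variant(vid)
            res = harmonize_variant(ea, oa, str(rec["ref"]), str(rec["alt"]))
        else:
            res = harmonize_variant(ea, oa, None, None)
        report.append((model.gene_id, vid, res.status))
        if not res.usable:
            continue
        d = panel.dosage(vid)
        pred += w * (2.0 - d if res.swap_dosage else d)
        n_found += 1
    report_df = pd.DataFrame(report, columns=["gene_id", "variant_id", "status"])
    if n_found == 0:
        raise ValueError(
            f"{model.gene_id}: all {len(model.weights)} modeled variants "
            "missing or dropped"
        )
    return pred, report_df


@dataclass
class ImputedExpressionMatrix:
    """Subjects x genes predicted expression with per-gene variant accounting."""

    values: pd.DataFrame  # subjects x genes
    report: pd.DataFrame  # gene_id, variant_id, status
    dropped_genes: pd.DataFrame  # gene_id, reason

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def impute_transcriptome(
    model_db: ModelDatabase, panel: GenotypePanel
) -> ImputedExpressionMatrix:
    """Apply every model in the database to a cohort panel.

    Genes whose modeled variants are all missing/dropped are excluded and
    logged. Output is deterministic and independent of panel variant order.
    """
    if len(model_db) == 0:
        raise ValueError("empty model database")
    cols, reports, dropped = {}, [], []
    for gene_id in sorted(model_db.genes()):
        try:
            pred, rep = impute_gene_expression(model_db[gene_id], panel)
        except ValueError as exc:
            dropped.append((gene_id, str(exc)))
            continue
        cols[gene_id] = pred
        reports.append(rep)
    values = pd.DataFrame(cols, index=panel.subjects)
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["gene_id", "variant_id", "status"])
    )
    return ImputedExpressionMatrix(
        values=values,
        report=report,
        dropped_genes=pd.DataFrame(dropped, columns=["gene_id", "reason"]),
    )
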