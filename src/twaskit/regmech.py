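"""Regulatory-mechanism interpretation of modeled eQTLs.

Covers LD-proxy expansion, TFBS evidence tiers (prostate-line ChIP-Seq
strongest, PWM prediction weakest), Fisher/bootstrap-OR enrichment against
background genes, a rank-weighted allele-specific binding score whose sign
gives the binding-favored allele, exact binomial concordance between
binding- and expression-increasing alleles, variant/peak overlap tallies
against a null variant sample, and virtual-4C coverage of the extreme
modeled eQTLs.

Coordinate conventions: variant positions are 1-based; peak intervals are
BED-style 0-based half-open. Conversion happens exactly once, at the overlap
query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

SOURCE_CATEGORY = {
    "chipseq_prostate": 1,
    "dnase_prostate": 2,
    "chipseq_other": 3,
    "dnase_other": 4,
    "motif_pwm": 4,
}


# ---------------------------------------------------------------------------
# LD proxies and evidence tiers


@dataclass
class LDProxySet:
    index_variant: str
    proxies: list[tuple[str, float]]  # (variant_id, r2), index included at 1.0
    threshold: float

    @property
    def variant_ids(self) -> list[str]:
        return [v for v, _ in self.proxies]


def expand_ld_proxies(
    variant_id: str, ld_r2: pd.DataFrame, r2_min: float = 0.8
) -> LDProxySet:
    """All variants with r2 >= ``r2_min`` to the index (index always included)."""
    if variant_id not in ld_r2.index:
        raise KeyError(f"{variant_id} absent from LD matrix")
    row = ld_r2.loc[variant_id]
    proxies = [(variant_id, 1.0)]
    for v, r2 in row.items():
        if v != variant_id and r2 >= r2_min:
            proxies.append((v, float(r2)))
    return LDProxySet(variant_id, proxies, r2_min)


def categorize_tfbs_evidence(
    annotations: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Best (minimum) evidence category per variant and per gene.

    ``annotations`` needs columns ``gene_id``, ``variant_id`` and ``source``
    (one of chipseq_prostate, dnase_prostate, chipseq_other, dnase_other,
    motif_pwm). Returns (per-variant, per-gene) category Series.
    """
    unknown = set(annotations["source"]) - set(SOURCE_CATEGORY)
    if unknown:
        raise ValueError(f"unknown evidence sources: {sorted(unknown)}")
    cats = annotations.assign(
        category=annotations["source"].map(SOURCE_CATEGORY)
    )
    per_variant = cats.groupby("variant_id")["category"].min()
    per_gene = cats.groupby("gene_id")["category"].min()
    return per_variant, per_gene


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float
    point_or: float
    boot_or_median: float
    boot_or_ci: tuple[float, float]
    n_boot: int
    seed: int


def tfbs_enrichment_test(
    table, n_boot: int = 10_000, seed: int = 0
) -> EnrichmentResult:
    """Two-sided Fisher exact test plus a gene-resampling bootstrap OR.

    ``table`` is [[a, b], [c, d]]: evidence/no-evidence counts for the genes
    of interest (row 1) and background genes (row 2). The bootstrap resamples
    each group independently with replacement, recomputing the OR with a
    Haldane 0.5 correction on zero cells, and reports the median and
    2.5/97.5 percentiles.
    """
    (a, b), (c, d) = [[int(v) for v in row] for row in table]
    if min(a + b, c + d) == 0:
        raise ValueError("each group must be non-empty")
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    point = _odds_ratio(a, b, c, d)

    rng = np.random.default_rng(seed)
    n1, n2 = a + b, c + d
    a_boot = rng.binomial(n1, a / n1, size=n_boot)
    c_boot = rng.binomial(n2, c / n2, size=n_boot)
    ors = np.array(
        [_odds_ratio(ab, n1 - ab, cb, n2 - cb) for ab, cb in zip(a_boot, c_boot)]
    )
    lo, hi = np.percentile(ors, [2.5, 97.5])
    return EnrichmentResult(
        table=((a, b), (c, d)),
        fisher_p=fisher_p,
        point_or=point,
        boot_or_median=float(np.median(ors)),
        boot_or_ci=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
    )


def _odds_ratio(a, b, c, d) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


# ---------------------------------------------------------------------------
# allele-specific binding


@dataclass
class BindingAffinityProfile:
    """Per-variant log10 binding-affinity p-values for two alleles.

    ``matrices`` holds (matrix_id, binding_rank >= 1, log10_p_allele1,
    log10_p_allele2). A more negative log10 p means stronger predicted
    binding.
    """

    variant_id: str
    allele1: str
    allele2: str
    matrices: list[tuple[str, int, float, float]]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("profile needs at least one matrix entry")
        if any(rank < 1 for _, rank, _, _ in self.matrices):
            raise ValueError("binding ranks must be >= 1")

    def swapped(self) -> "BindingAffinityProfile":
        return BindingAffinityProfile(
            self.variant_id,
            self.allele2,
            self.allele1,
            [(m, r, p2, p1) for m, r, p1, p2 in self.matrices],
        )


def binding_direction_score(profile: BindingAffinityProfile) -> float:
    """Rank-weighted allele difference in log10 binding p-values.

    score = sum over matrices of (1/sqrt(rank)) * (log10 p_A1 - log10 p_A2).
    Because stronger binding means a more negative log10 p, a negative score
    means allele1 is the binding-favored allele. Downstream concordance uses
    only the sign.
    """
    return float(
        sum(
            (p1 - p2) / np.sqrt(rank)
            for _, rank, p1, p2 in profile.matrices
        )
    )


def concordance_binomial_test(
    n_concordant: int, n_total: int, p0: float = 0.5
) -> float:
    """Exact two-sided binomial p (minimum-likelihood convention).

    Sums P(k) over all k with P(k) <= P(n_concordant); at p0 = 0.5 this
    coincides with doubling the one-sided tail (up to the final-term
    convention).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_concordant <= n_total:
        raise ValueError("n_concordant out of range")
    return float(stats.binomtest(n_concordant, n_total, p0).pvalue)


# ---------------------------------------------------------------------------
# peak overlap


class PeakSet:
    """Named genomic intervals (0-based half-open) with a sample label each."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.n_intervals = 0

    @classmethod
    def from_records(cls, records) -> "PeakSet":
        """records: iterable of (chromosome, start, end, sample_label)."""
        ps = cls()
        for chrom, start, end, label in records:
            ps.add(str(chrom), int(start), int(end), str(label))
        return ps

    @classmethod
    def from_bed(cls, path) -> "PeakSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        )
        return cls.from_records(df.itertuples(index=False))

    def add(self, chrom: str, start: int, end: int, label: str) -> None:
        if not start < end:
            raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
        self.n_intervals += 1

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def count_overlaps(self, chrom: str, position_1based: int) -> int:
        """Number of intervals (across all samples) containing a 1-based
        variant position, under the half-open BED convention."""
        tree = self._trees.get(str(chrom))
        if tree is None:
            return 0
        return len(tree[position_1based - 1])


def tally_peak_overlap(
    variants: pd.DataFrame,
    peaks: PeakSet,
    null_variants: pd.DataFrame | None = None,
) -> dict:
    """Per-variant peak-overlap tallies, optionally compared to a null sample.

    ``variants`` (and ``null_variants``) need columns ``chromosome`` and
    ``position`` (1-based) and may carry a ``variant_id`` column or index.
    Raises when a query chromosome has no peak data at all and no chromosome
    matches (naming mismatch). The comparison reports both a
    Mann-Whitney-Wilcoxon and a Welch t statistic.
    """
    chroms = set(variants["chromosome"].astype(str))
    if peaks.chromosomes and not (chroms & peaks.chromosomes):
        raise ValueError(
            "chromosome naming mismatch: no query chromosome found in peaks; "
            f"unmatched: {sorted(chroms)}"
        )
    tallies = np.array(
        [
            peaks.count_overlaps(str(r.chromosome), int(r.position))
            for r in variants.itertuples()
        ]
    )
    out = {
        "tallies": tallies,
        "mean": float(tallies.mean()),
        "sd": float(tallies.std(ddof=1)) if len(tallies) > 1 else 0.0,
    }
    if null_variants is not None:
        null_tallies = np.array(
            [
                peaks.count_overlaps(str(r.chromosome), int(r.position))
                for r in null_variants.itertuples()
            ]
        )
        out["null_tallies"] = null_tallies
        out["null_mean"] = float(null_tallies.mean())
        if np.all(tallies == tallies[0]) and np.all(null_tallies == tallies[0]):
            out["mannwhitney_p"] = 1.0
            out["ttest_p"] = 1.0
        else:
            out["mannwhitney_p"] = float(
                stats.mannwhitneyu(tallies, null_tallies, alternative="two-sided")[1]
            )
            out["ttest_p"] = float(
                stats.ttest_ind(tallies, null_tallies, equal_var=False)[1]
            )
    return out


def sample_null_variants(
    site_list: pd.DataFrame, n: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Seeded uniform draw (with replacement if needed) from a variant site list."""
    rng = np.random.default_rng(seed)
    replace = n > len(site_list)
    idx = rng.choice(len(site_list), size=n, replace=replace)
    return site_list.iloc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# virtual 4C


@dataclass
class VirtualFourCTrack:
    """Anchored Hi-C read-density histogram over contiguous fixed-width bins."""

    anchor_gene: str
    chromosome: str
    bin_start: int  # 0-based start of the first bin
    bin_width: int
    densities: np.ndarray
    anchor_bin: int = field(default=0)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != 1 or self.densities.size == 0:
            raise ValueError("track must be a non-empty 1-D density vector")
        if np.any(self.densities < 0):
            raise ValueError("densities must be >= 0")
        if not 0 <= self.anchor_bin < self.densities.size:
            raise ValueError("anchor bin outside track")

    def bin_of(self, position_1based: int) -> int:
        return (position_1based - 1 - self.bin_start) // self.bin_width


def virtual4c_coverage(
    track: VirtualFourCTrack, eqtl_positions
) -> dict:
    """Do the extreme modeled eQTLs fall inside the anchor's contact span?

    The contact span is the maximal contiguous run of bins with density > 0
    containing the anchor bin. Coverage is true iff both the
    furthest-upstream and furthest-downstream eQTL positions land inside it.
    Reports the bin distance from each extreme eQTL to the nearer span edge
    (negative when outside).
    """
    pos = np.asarray(sorted(eqtl_positions))
    if pos.size == 0:
        raise ValueError("no eQTL positions supplied")
    dens = track.densities
    a = track.anchor_bin
    if dens[a] == 0:
        return {"covered": False, "flag": "anchor bin has zero density"}
    lo = a
    while lo > 0 and dens[lo - 1] > 0:
        lo -= 1
    hi = a
    while hi < dens.size - 1 and dens[hi + 1] > 0:
        hi += 1
    up_bin = track.bin_of(int(pos[0]))
    down_bin = track.bin_of(int(pos[-1]))
    covered = lo <= up_bin <= hi and lo <= down_bin <= hi
    return {
        "covered": bool(covered),
        "span_bins": (int(lo), int(hi)),
        "upstream_margin_bins": int(up_bin - lo),
        "downstream_margin_bins": int(hi - down_bin),
    }
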