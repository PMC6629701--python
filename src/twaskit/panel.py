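"""Genotype dosage panels.

A :class:`GenotypePanel` holds a subjects x variants matrix of alternate-allele
dosages in [0, 2] together with per-variant metadata (chromosome, 1-based
position, ref/alt alleles, imputation INFO r2). It is the common currency
between the synthetic-data generator, cis-model training, and transcriptome
imputation.

On-disk interchange is a dosage TSV (variants as rows, metadata columns then
one column per subject) or a minimal VCF with a ``DS`` FORMAT field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_META_COLS = ["variant_id", "chromosome", "position", "ref", "alt", "info_r2"]


@dataclass
class GenotypePanel:
    """Subjects x variants alternate-allele dosage matrix with variant metadata.

    Parameters
    ----------
    variants
        DataFrame indexed by ``variant_id`` with columns ``chromosome``,
        ``position`` (1-based), ``ref``, ``alt`` and ``info_r2``.
    dosages
        Array of shape ``(n_subjects, n_variants)`` with values in [0, 2];
        column order matches ``variants``.
    subjects
        Subject identifiers, length ``n_subjects``.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.variants)} variant records"
            )
        if not self.subjects:
            self.subjects = [f"S{i:06d}" for i in range(self.dosages.shape[0])]
        if len(self.subjects) != self.dosages.shape[0]:
            raise ValueError("subject count does not match dosage rows")
        self._col = {v: i for i, v in enumerate(self.variants.index)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col

    def dosage(self, variant_id: str) -> np.ndarray:
        """Alt-allele dosage vector for one variant (float64 copy)."""
        return np.asarray(self.dosages[:, self._col[variant_id]], dtype=float)

    def variant(self, variant_id: str) -> pd.Series:
        return self.variants.loc[variant_id]

    def subset(self, variant_ids) -> "GenotypePanel":
        idx = [self._col[v] for v in variant_ids]
        return GenotypePanel(
            variants=self.variants.iloc[idx].copy(),
            dosages=self.dosages[:, idx],
            subjects=list(self.subjects),
        )

    def take_subjects(self, rows) -> "GenotypePanel":
        rows = np.asarray(rows)
        return GenotypePanel(
            variants=self.variants.copy(),
            dosages=self.dosages[rows],
            subjects=[self.subjects[i] for i in rows],
        )

    # -- LD ----------------------------------------------------------------

    def ld_r2(self, variant_ids=None) -> pd.DataFrame:
        """Pairwise squared Pearson correlation of dosages.

        Monomorphic variants get r2 = 0 with everything (and 1 with
        themselves) rather than NaN.
        """
        ids = list(variant_ids) if variant_ids is not None else list(self.variants.index)
        X = np.asarray(
            self.dosages[:, [self._col[v] for v in ids]], dtype=float
        )
        X = X - X.mean(axis=0)
        sd = X.std(axis=0)
        ok = sd > 0
        Xn = np.zeros_like(X)
        Xn[:, ok] = X[:, ok] / sd[ok]
        r = (Xn.T @ Xn) / X.shape[0]
        r2 = r**2
        np.fill_diagonal(r2, 1.0)
        return pd.DataFrame(r2, index=ids, columns=ids)

    # -- I/O -----------------------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        df = self.variants.reset_index()
        if "variant_id" not in df.columns:
            df = df.rename(columns={"index": "variant_id"})
        dos = pd.DataFrame(
            np.asarray(self.dosages, dtype=float).T, columns=self.subjects
        )
        pd.concat([df[_META_COLS], dos], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"dosage TSV missing metadata columns: {missing}")
        subjects = [c for c in df.columns if c not in _META_COLS]
        variants = df[_META_COLS].set_index("variant_id")
        dosages = df[subjects].to_numpy(dtype=float).T
        return cls(variants=variants, dosages=dosages, subjects=subjects)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with per-sample DS (dosage) values."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Alternate allele dosage">\n'
            )
            fh.write(
                '##INFO=<ID=INFO_R2,Number=1,Type=Float,'
                'Description="Imputation INFO r2">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.subjects)
                + "\n"
            )
            dos = np.asarray(self.dosages, dtype=float)
            for j, (vid, row) in enumerate(self.variants.iterrows()):
                ds = "\t".join(f"{d:g}" for d in dos[:, j])
                fh.write(
                    f"{row.chromosome}\t{int(row.position)}\t{vid}\t{row.ref}\t"
                    f"{row.alt}\t.\t.\tINFO_R2={row.info_r2:g}\tDS\t{ds}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read a DS-dosage VCF of the form this package writes."""
        meta, rows, dos = None, [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    meta = line.rstrip("\n").split("\t")
                    continue
                f = line.rstrip("\n").split("\t")
                info_r2 = 1.0
                for kv in f[7].split(";"):
                    if kv.startswith("INFO_R2="):
                        info_r2 = float(kv.split("=", 1)[1])
                fmt = f[8].split(":")
                ds_i = fmt.index("DS")
                rows.append((f[2], f[0], int(f[1]), f[3], f[4], info_r2))
                dos.append([float(s.split(":")[ds_i]) for s in f[9:]])
        if meta is None:
            raise ValueError("no #CHROM header line in VCF")
        variants = pd.DataFrame(
            rows, columns=_META_COLS
        ).set_index("variant_id")
        return cls(
            variants=variants,
            dosages=np.asarray(dos, dtype=float).T,
            subjects=meta[9:],
        )
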