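"""Genotype container and on-disk formats.

Dosages count copies of the ALT allele (0/1/2), stored as float with NaN for
missing calls. Positions are 1-based (VCF convention); chromosome labels are
kept without a ``chr`` prefix internally but the prefix is tolerated on input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "rsid", "ref", "alt"]


@dataclass
class GenotypeSet:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos, rsid, ref, alt
        Positions must be sorted within chromosome and (chrom, pos, ref, alt)
        unique.
    dosages : float ndarray, shape (n_samples, n_variants)
        Entries in {0, 1, 2} or NaN for missing.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.variants["chrom"] = (
            self.variants["chrom"].astype(str).str.replace("^chr", "", regex=True)
        )
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        key = self.variants[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, ref, alt) variant records")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Per-variant (n_hom_ref, n_het, n_hom_alt) over non-missing calls."""
        counts = np.empty((self.n_variants, 3), dtype=int)
        for k, g in enumerate((0.0, 1.0, 2.0)):
            counts[:, k] = np.nansum(self.dosages == g, axis=0)
        return counts

    def subset_variants(self, index) -> "GenotypeSet":
        index = np.asarray(index)
        return GenotypeSet(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, keep_ids) -> "GenotypeSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep_ids]
        return GenotypeSet(
            sample_ids=list(keep_ids),
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )

    # ---------------------------------------------------------------- I/O

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 file with GT-only genotype fields."""
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=neuroslope\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in self.variants["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            for j, rec in self.variants.iterrows():
                gts = "\t".join(
                    "./." if np.isnan(d) else gt_map[d] for d in self.dosages[:, j]
                )
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t{rec.rsid}\t{rec.ref}\t{rec.alt}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeSet":
        """Read GT fields from a VCF file via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        sample_ids = list(vcf.samples)
        rows, cols = [], []
        for var in vcf:
            alt = var.ALT[0] if var.ALT else "."
            rows.append((var.CHROM, var.POS, var.ID or ".", var.REF, alt))
            g = var.gt_types.astype(float)  # 0,1,2 and 3 == unknown
            g[g == 3] = np.nan
            cols.append(g)
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
        return cls(sample_ids=sample_ids, variants=variants, dosages=dosages)

    def to_dosage_tsv(self, path) -> None:
        """Dosage TSV dialect: variant metadata columns then one column per sample."""
        df = self.variants.copy()
        mat = pd.DataFrame(self.dosages.T, columns=self.sample_ids)
        pd.concat([df, mat], axis=1).to_csv(
            path, sep="\t", index=False, na_rep=".", float_format="%g"
        )

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeSet":
        df = pd.read_csv(path, sep="\t", na_values=".")
        sample_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
        return cls(
            sample_ids=sample_ids,
            variants=df[VARIANT_COLUMNS].copy(),
            dosages=df[sample_ids].to_numpy(dtype=float).T,
        )
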