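"""Genotype matrices (allele dosages) and site-level filtering.

Genotypes are stored as an individuals x sites matrix of minor-allele
dosages in {0, 1, 2}, with NaN marking missing calls. I/O supports a
biallelic-SNP VCF (GT field; read through cyvcf2, written as plain VCFv4.2
text) and a TSV dosage table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "filter_sites"]


@dataclass
class GenotypeMatrix:
    """Individuals x sites allele-dosage matrix with sample metadata.

    ``dosages`` is float so NaN can mark missing calls; defined entries are
    0, 1 or 2 copies of the alternate allele.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    site_ids: list[str]
    range_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x sites array")
        n, m = self.dosages.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.site_ids = [str(s) for s in self.site_ids]
        if len(self.sample_ids) != n or len(self.site_ids) != m:
            raise ValueError("id lists do not match dosage dimensions")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.site_ids)) != m:
            raise ValueError("site_ids must be unique")
        defined = self.dosages[np.isfinite(self.dosages)]
        if defined.size and not np.isin(defined, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if self.range_labels is not None:
            self.range_labels = np.asarray(self.range_labels)
            if self.range_labels.shape[0] != n:
                raise ValueError("range_labels length does not match samples")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.nonzero(mask)[0]
        return GenotypeMatrix(
            self.dosages[idx],
            [self.sample_ids[i] for i in idx],
            list(self.site_ids),
            None if self.range_labels is None else self.range_labels[idx],
        )

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            [self.site_ids[i] for i in idx],
            self.range_labels,
        )

    def allele_freqs(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_vcf(cls, path, range_labels=None) -> "GenotypeMatrix":
        """Read biallelic SNP genotypes (GT field) from a VCF via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        site_ids: list[str] = []
        rows: list[np.ndarray] = []
        for var in vcf:
            if len(var.ALT) != 1:
                continue  # biallelic SNPs only
            name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            site_ids.append(name)
            gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown
            gt[gt == 3] = np.nan
            rows.append(gt)
        dosages = (np.column_stack(rows) if rows
                   else np.empty((len(samples), 0)))
        return cls(dosages, samples, site_ids, range_labels)

    def write_vcf(self, path) -> None:
        """Write a minimal VCFv4.2 with GT only (synthetic positions)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.sample_ids) + "\n")
            gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, site in enumerate(self.site_ids):
                col = self.dosages[:, j]
                gts = "\t".join("./." if np.isnan(v) else gt_strings[v] for v in col)
                fh.write(f"1\t{j + 1}\t{site}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def read_tsv(cls, path, range_labels=None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), range_labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.dosages, index=self.sample_ids,
                     columns=self.site_ids).to_csv(path, sep="\t")


def filter_sites(g: GenotypeMatrix, min_maf: float = 0.05,
                 max_missing: float = 0.0) -> GenotypeMatrix:
    """Retain sites with MAF >= min_maf and missing fraction <= max_missing.

    MAF is the minor-allele frequency computed on non-missing calls.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    freq = g.allele_freqs()
    maf = np.minimum(freq, 1.0 - freq)
    miss = g.missing_fraction()
    with np.errstate(invalid="ignore"):
        keep = (miss <= max_missing) & np.isfinite(maf) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("all sites removed by filtering; result is empty")
    return g.subset_sites(keep)
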