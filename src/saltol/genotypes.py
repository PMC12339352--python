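"""Genotype container and marker-level I/O.

Dosage coding is the alt-allele count (0/1/2) with ``NaN`` for missing
calls.  Markers carry a map (chromosome, 1-based position, ref/alt) that is
kept sorted with strictly increasing positions within each chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MARKER_COLS = ["marker", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Accession x marker dosage matrix plus marker map.

    Parameters
    ----------
    dosages : DataFrame
        Rows indexed by accession id, columns by marker id, values in
        {0, 1, 2, NaN}.
    markers : DataFrame
        One row per marker with columns ``marker, chrom, pos, ref, alt``;
        order matches the dosage columns.
    """

    dosages: pd.DataFrame
    markers: pd.DataFrame
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.markers["marker"]):
            raise ValueError("dosage columns and marker map out of sync")
        for _, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def accessions(self) -> pd.Index:
        return self.dosages.index

    def allele_freq(self) -> pd.Series:
        """Alt-allele frequency per marker, over non-missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Dosage array with missing calls replaced by the marker mean."""
        m = self.dosages.to_numpy(dtype=float)
        col_mean = np.nanmean(m, axis=0)
        idx = np.where(np.isnan(m))
        m[idx] = col_mean[idx[1]]
        return m

    def filter_markers(self, maf_min: float = 0.05, missing_max: float = 0.2) -> "GenotypeMatrix":
        """Drop markers below a MAF floor or above a missingness ceiling."""
        if not 0.0 <= maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 <= missing_max <= 1.0:
            raise ValueError("missing_max must lie in [0, 1]")
        maf = self.maf()
        miss = self.missing_rate()
        low_maf = maf < maf_min if maf_min > 0 else pd.Series(False, index=maf.index)
        high_miss = miss > missing_max
        keep = ~(low_maf | high_miss)
        if not keep.any():
            raise ValueError("no markers pass the MAF/missingness filters")
        report = {
            "n_input": int(self.n_markers),
            "n_removed_maf": int(low_maf.sum()),
            "n_removed_missing": int((high_miss & ~low_maf).sum()),
            "n_kept": int(keep.sum()),
        }
        logger.info("marker filter: %s", report)
        kept_ids = keep.index[keep.to_numpy()]
        out = GenotypeMatrix(
            self.dosages.loc[:, kept_ids],
            self.markers[self.markers["marker"].isin(kept_ids)].reset_index(drop=True),
        )
        out.filter_report = report
        return out

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        """Accessions x markers dosage table; missing written as NA."""
        self.dosages.to_csv(path, sep="\t", index_label="accession", na_rep="NA")

    def to_vcf(self, path) -> None:
        """Minimal VCF 4.2 with unphased GT calls."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom, grp in self.markers.groupby("chrom", sort=False):
                fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
            samples = "\t".join(self.accessions)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            dos = self.dosages.to_numpy(dtype=float)
            for j, rec in enumerate(self.markers.itertuples(index=False)):
                calls = "\t".join(
                    "./." if np.isnan(d) else gt_map[d] for d in dos[:, j]
                )
                fh.write(
                    f"{rec.chrom}\t{int(rec.pos)}\t{rec.marker}\t{rec.ref}\t{rec.alt}"
                    f"\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="accession", na_values=["NA"])
        markers = _marker_map_from_ids(df.columns)
        return cls(df.astype(float), markers)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic SNP dosages from a VCF (GT field).

        Multiallelic records are skipped with a warning; ``./.`` becomes NaN.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows: list[np.ndarray] = []
        meta: list[tuple] = []
        n_multi = 0
        for var in vcf:
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = var.gt_types.astype(float)
            dose = np.where(gt == 3, 2.0, gt)
            dose[gt == 2] = np.nan
            rows.append(dose)
            mid = var.ID if var.ID not in (None, ".") else f"S{var.CHROM}_{var.POS}"
            meta.append((mid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        vcf.close()
        if n_multi:
            warnings.warn(f"skipped {n_multi} multiallelic records")
        if not rows:
            raise ValueError(f"no biallelic SNP records found in {path}")
        markers = pd.DataFrame(meta, columns=_MARKER_COLS)
        dosages = pd.DataFrame(
            np.column_stack(rows), index=pd.Index(samples, name="accession"),
            columns=markers["marker"],
        )
        return cls(dosages, markers)


def _marker_map_from_ids(ids) -> pd.DataFrame:
    """Recover (chrom, pos) from 'S<chrom>_<pos>' marker ids of a TSV mirror."""
    rows = []
    for mid in ids:
        try:
            chrom, pos = mid.lstrip("S").split("_")
            rows.append((mid, chrom, int(pos), "N", "N"))
        except ValueError as exc:  # pragma: no cover - malformed header
            raise ValueError(f"cannot parse marker id {mid!r}") from exc
    return pd.DataFrame(rows, columns=_MARKER_COLS)


def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF reader, otherwise TSV mirror."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return GenotypeMatrix.from_vcf(p)
    return GenotypeMatrix.from_tsv(p)
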