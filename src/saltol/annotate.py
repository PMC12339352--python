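"""Candidate-region gene lookup and region-level variant classification.

Around each associated marker a window of +/- 150 kb (the reported
linkage-disequilibrium decay distance in temperate japonica rice) is
screened against the gene models: overlapping genes, the nearest gene and
its distance (0 with an exon/intron context when the marker falls inside a
gene), and a region-level classification of the polymorphic sites
(exonic / intronic / intergenic; SNP vs InDel).  Coordinates are 1-based
inclusive throughout, matching GFF3/VCF conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genes import GeneModels

DEFAULT_WINDOW = 150_000


@dataclass
class CandidateRegion:
    """Genes and distances within a window around one associated marker."""

    marker: str
    chrom: str
    pos: int
    window: tuple                    # (start, end), clipped at 1
    genes: pd.DataFrame              # gene_id, start, end, strand, distance
    nearest_gene: str = None
    nearest_distance: int = None
    context: str = None              # 'exon' | 'intron' when distance == 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def summary(self) -> dict:
        return {
            "marker": self.marker, "chrom": self.chrom, "pos": self.pos,
            "window_start": self.window[0], "window_end": self.window[1],
            "n_genes": self.n_genes, "nearest_gene": self.nearest_gene,
            "nearest_distance": self.nearest_distance, "context": self.context,
        }


def _span_distance(pos: int, start: int, end: int) -> int:
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def candidate_region(marker, gene_models: GeneModels,
                     window: int = DEFAULT_WINDOW) -> CandidateRegion:
    """Genes intersecting [pos - window, pos + window] around a marker.

    ``marker`` is a mapping or namedtuple-like with ``marker/chrom/pos``
    fields.  Window edges are inclusive and clipped at coordinate 1; the
    nearest gene is the minimal span distance, ties broken by the lower
    start coordinate, and a distance of 0 carries an exon/intron context.
    """
    get = marker.get if hasattr(marker, "get") else lambda k: getattr(marker, k)
    mid, chrom, pos = str(get("marker")), str(get("chrom")), int(get("pos"))
    chrom_genes = gene_models.genes[gene_models.genes["chrom"] == chrom]
    if chrom not in set(gene_models.genes["chrom"]):
        raise ValueError(f"chromosome {chrom!r} absent from gene models")
    lo, hi = max(1, pos - window), pos + window
    hit = chrom_genes[(chrom_genes["end"] >= lo) & (chrom_genes["start"] <= hi)].copy()
    hit["distance"] = [
        _span_distance(pos, s, e) for s, e in zip(hit["start"], hit["end"])
    ]
    hit = hit.sort_values(["distance", "start"], kind="stable").reset_index(drop=True)

    nearest = dist = context = None
    if len(hit):
        nearest = hit.iloc[0]["gene_id"]
        dist = int(hit.iloc[0]["distance"])
        if dist == 0:
            exons = gene_models.exons[gene_models.exons["gene_id"] == nearest]
            inside_exon = ((exons["start"] <= pos) & (pos <= exons["end"])).any()
            context = "exon" if inside_exon else "intron"
    return CandidateRegion(
        marker=mid, chrom=chrom, pos=pos, window=(lo, hi),
        genes=hit[["gene_id", "start", "end", "strand", "distance"]],
        nearest_gene=nearest, nearest_distance=dist, context=context,
    )


def classify_variants(variants: pd.DataFrame, gene_models: GeneModels) -> dict:
    """Label variants exonic / intronic / intergenic and SNP vs InDel.

    ``variants`` needs columns chrom, pos, ref, alt.  A position inside
    any exon is exonic; inside a gene but outside exons is intronic
    (priority exon > intron); otherwise intergenic.  Any allele of length
    != 1 makes the site an InDel.  Returns the labelled table plus counts.
    """
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in variants.columns:
            raise ValueError(f"variants table lacks column {col!r}")
    exon_trees: dict = {}
    gene_trees: dict = {}
    for chrom, grp in gene_models.exons.groupby("chrom"):
        exon_trees[chrom] = IntervalTree.from_tuples(
            (s, e + 1) for s, e in zip(grp["start"], grp["end"]))
    for chrom, grp in gene_models.genes.groupby("chrom"):
        gene_trees[chrom] = IntervalTree.from_tuples(
            (s, e + 1) for s, e in zip(grp["start"], grp["end"]))

    regions, kinds = [], []
    for rec in variants.itertuples(index=False):
        chrom, pos = str(rec.chrom), int(rec.pos)
        if chrom in exon_trees and exon_trees[chrom][pos]:
            regions.append("exonic")
        elif chrom in gene_trees and gene_trees[chrom][pos]:
            regions.append("intronic")
        else:
            regions.append("intergenic")
        kinds.append("SNP" if len(str(rec.ref)) == 1 and len(str(rec.alt)) == 1
                     else "InDel")
    labelled = variants.copy()
    labelled["region"] = regions
    labelled["kind"] = kinds
    counts = {
        "exonic": regions.count("exonic"),
        "intronic": regions.count("intronic"),
        "intergenic": regions.count("intergenic"),
        "SNP": kinds.count("SNP"),
        "InDel": kinds.count("InDel"),
        "total": len(regions),
    }
    return {"variants": labelled, "counts": counts}


def annotate_significant(result, gene_models: GeneModels, genotypes=None,
                         window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Associated-marker annotation table in the reporting layout.

    One row per significant marker: position, p, -log10 p, nearest gene
    with distance/context, gene count in the window, and (when the
    genotype matrix is given) the count of polymorphic sites falling in
    the window.
    """
    rows = []
    for rec in result.significant.itertuples(index=False):
        region = candidate_region(
            {"marker": rec.marker, "chrom": rec.chrom, "pos": rec.pos},
            gene_models, window=window)
        n_snps = None
        if genotypes is not None:
            mk = genotypes.markers
            n_snps = int(((mk["chrom"].astype(str) == str(rec.chrom))
                          & (mk["pos"] >= region.window[0])
                          & (mk["pos"] <= region.window[1])).sum())
        nearest = region.nearest_gene
        if nearest is not None:
            tag = ("Intron" if region.context == "intron"
                   else "Exon" if region.context == "exon"
                   else f"{region.nearest_distance} bp")
            nearest = f"{nearest} ({tag})"
        rows.append({
            "marker": rec.marker, "chrom": rec.chrom, "pos": rec.pos,
            "p": rec.p, "neglog10p": rec.neglog10p,
            "nearest_gene": nearest, "n_genes": region.n_genes,
            "n_snps_window": n_snps,
        })
    return pd.DataFrame(rows)
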