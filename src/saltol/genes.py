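"""Gene-model container backed by GFF3 (1-based, inclusive coordinates)."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand"]
_EXON_COLS = ["gene_id", "chrom", "start", "end", "exon_number"]


@dataclass
class GeneModels:
    """Genes and their exons.

    ``genes`` has columns ``gene_id, chrom, start, end, strand``;
    ``exons`` has ``gene_id, chrom, start, end, exon_number``.
    Exons always lie within their gene's span.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes[_GENE_COLS].reset_index(drop=True)
        self.exons = self.exons[_EXON_COLS].reset_index(drop=True)
        bounds = self.exons.merge(self.genes, on="gene_id", suffixes=("", "_gene"))
        bad = (bounds["start"] < bounds["start_gene"]) | (bounds["end"] > bounds["end_gene"])
        if bad.any():
            raise ValueError("exon outside its gene bounds")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def chromosomes(self) -> list:
        return list(self.genes["chrom"].unique())

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            exons_by_gene = {g: df for g, df in self.exons.groupby("gene_id")}
            for g in self.genes.itertuples(index=False):
                fh.write(
                    f"{g.chrom}\tsaltol\tgene\t{int(g.start)}\t{int(g.end)}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                for e in exons_by_gene.get(g.gene_id, pd.DataFrame()).itertuples(index=False):
                    fh.write(
                        f"{e.chrom}\tsaltol\texon\t{int(e.start)}\t{int(e.end)}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.exon{int(e.exon_number)};"
                        f"Parent={g.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path) -> "GeneModels":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes, exons = [], []
        for feat in db.features_of_type("gene"):
            genes.append((feat.id, feat.seqid, feat.start, feat.end, feat.strand))
        for feat in db.features_of_type("exon"):
            parent = feat.attributes["Parent"][0]
            num = int(feat.id.rsplit("exon", 1)[-1]) if "exon" in feat.id else 1
            exons.append((parent, feat.seqid, feat.start, feat.end, num))
        gdf = pd.DataFrame(genes, columns=_GENE_COLS).sort_values(
            ["chrom", "start"], kind="stable"
        )
        edf = pd.DataFrame(exons, columns=_EXON_COLS).sort_values(
            ["gene_id", "exon_number"], kind="stable"
        )
        return cls(gdf, edf)
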