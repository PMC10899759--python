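"""Readers and writers for the plain-text formats the pipeline exchanges.

Internal coordinate convention is 0-based half-open everywhere (BED native);
GFF3 (1-based, closed) is converted at the boundary.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_SOURCE = "mirisc_shift"


@dataclass
class GeneModel:
    """A gene's exon/intron structure and 3'UTR in genome coordinates.

    ``exons`` are sorted, non-overlapping 0-based half-open intervals;
    ``utr3`` is the 3'UTR interval, contained in the terminal exon
    (transcript orientation). The coordinate frame for eCLIP peaks and
    exon/intron count splitting.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr3: tuple[int, int] | None = None

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]

    def utr_sequence(self, genome: dict[str, str]) -> str:
        """Strand-aware 3'UTR sequence, 5'->3'."""
        if self.utr3 is None:
            raise ValueError(f"gene {self.gene_id} has no 3'UTR")
        s, e = self.utr3
        seq = genome[self.chrom][s:e]
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str | os.PathLike, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(path: str | os.PathLike, genes: list[GeneModel]) -> None:
    """Emit gene/exon/three_prime_UTR features (1-based, closed intervals)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        attr = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chrom, GFF3_SOURCE, "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", attr]
            )
        )
        for i, (s, e) in enumerate(sorted(g.exons), 1):
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        GFF3_SOURCE,
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                    ]
                )
            )
        if g.utr3 is not None:
            s, e = g.utr3
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        GFF3_SOURCE,
                        "three_prime_UTR",
                        str(s + 1),
                        str(e),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}.utr3;Parent={g.gene_id}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models back from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gm = GeneModel(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
        )
        for child in db.children(feat, featuretype="exon"):
            gm.exons.append((child.start - 1, child.end))
        for child in db.children(feat, featuretype="three_prime_UTR"):
            gm.utr3 = (child.start - 1, child.end)
        gm.exons.sort()
        genes.append(gm)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# BED6 + compartment column


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "compartment"]


def write_bed(path: str | os.PathLike, peaks: pd.DataFrame) -> None:
    """BED6 with a 7th ``compartment`` column (``cyto``/``nuc``)."""
    peaks[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# TSV matrices and tables


def write_counts(path: str | os.PathLike, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.astype(int)


def write_design(path: str | os.PathLike, design: pd.Series) -> None:
    design.rename("condition").to_csv(path, sep="\t", index_label="sample")


def read_design(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return df["condition"]


def write_table(path: str | os.PathLike, table: pd.DataFrame, float_format: str = "%.6g") -> None:
    table.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
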