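"""miRNA seed extraction, seed-family grouping, and 3'UTR seed-site scanning.

The seed is defined as miRNA nucleotides 2-8 (5'->3'); site types follow the
canonical strong-site convention:

* ``8mer``     -- perfect Watson-Crick match to the reverse complement of
  miRNA nt 2-8, followed by an A in the target.
* ``7mer-m8``  -- match to the reverse complement of nt 2-8 (no A required).
* ``7mer-A1``  -- match to the reverse complement of nt 2-7, followed by an A.

The position-1 A is a literal A in the target, not complementarity to miRNA
nt 1. Wobble (G:U) pairing is not counted; ambiguous bases never match.
Targets are handled in the DNA alphabet (U->T) and miRNAs in RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import GeneModel

log = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
#: ordering used when one offset satisfies several patterns
SITE_STRENGTH = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1}


def normalize_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def normalize_dna(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Mirna:
    """A mature miRNA; ``seed`` is nt 2-8 of the RNA sequence."""

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(f"{self.name}: mature miRNA length {len(self.sequence)} outside 18-26")
        if set(self.sequence) - set("ACGU"):
            raise ValueError(f"{self.name}: non-ACGU characters in sequence")

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)


@dataclass(frozen=True)
class SeedSite:
    """A seed-match site in a 3'UTR, 0-based half-open offsets."""

    utr_id: str
    start: int
    end: int
    site_type: str
    family_seed: str


@dataclass
class SeedFamily:
    """miRNAs sharing the nt 2-8 seed; the unit of top-k abundance selection."""

    seed: str
    members: list[str]
    expression_cpm: pd.Series | None = None
    rank: int | None = None


@dataclass
class EclipPeak:
    """An AGO2 occupancy interval (genome frame) with compartment label."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str
    compartment: str
    region: str | None = None
    sites: list[SeedSite] = field(default_factory=list)


def seed_of(mirna_sequence: str) -> str:
    """Return the 7-mer seed: characters at 1-based positions 2-8."""
    seq = normalize_rna(mirna_sequence)
    if len(seq) < 8:
        raise ValueError(f"sequence of length {len(seq)} too short for a nt 2-8 seed")
    return seq[1:8]


def sites_for_seed(utr_sequence: str, seed: str, utr_id: str = "") -> list[SeedSite]:
    """Scan a UTR (DNA, 5'->3') for strong sites of one 7-mer seed.

    Each offset is reported at most once with its strongest type; a 7mer-A1
    hit that is the tail of an 8mer is subsumed by the 8mer call.
    """
    u = normalize_dna(utr_sequence)
    seed_dna = normalize_dna(seed)
    if len(seed_dna) != 7:
        raise ValueError("seed must be a 7-mer")
    m8 = revcomp_dna(seed_dna)            # pairs miRNA nt 2-8
    a1 = revcomp_dna(seed_dna[:6]) + "A"  # pairs nt 2-7, then literal A
    eight = m8 + "A"
    seed_rna = seed_dna.replace("T", "U")
    sites = []
    for i in range(len(u) - 6):
        if u[i : i + 8] == eight:
            sites.append(SeedSite(utr_id, i, i + 8, "8mer", seed_rna))
        elif u[i : i + 7] == m8:
            sites.append(SeedSite(utr_id, i, i + 7, "7mer-m8", seed_rna))
        elif u[i : i + 7] == a1 and not (i >= 1 and u[i - 1 : i + 7] == eight):
            sites.append(SeedSite(utr_id, i, i + 7, "7mer-A1", seed_rna))
    return sites


def site_match(utr_sequence: str, mirna: Mirna, utr_id: str = "") -> list[SeedSite]:
    """All strong (8mer/7mer-m8/7mer-A1) seed sites of ``mirna`` in a UTR."""
    return sites_for_seed(utr_sequence, mirna.seed, utr_id=utr_id)


def group_families(
    mirnas: list[Mirna],
    smallrna_counts: pd.DataFrame | None = None,
    *,
    condition: pd.Series | None = None,
    use_condition: str | None = None,
    top_k: int | None = None,
) -> list[SeedFamily]:
    """Partition miRNAs by identical seed and rank families by abundance.

    Family CPM is the sum of member CPM (raw library-size CPM of the
    small-RNA matrix); rank is by mean CPM over the selected samples
    (default: all samples pooled). Ties break lexicographically by seed.
    miRNAs present in the count matrix but absent from the FASTA are
    excluded with a warning; returns all families ranked, or the top ``top_k``.
    """
    from .expression import cpm

    by_seed: dict[str, list[str]] = {}
    known = set()
    for m in mirnas:
        by_seed.setdefault(m.seed, []).append(m.name)
        known.add(m.name)
    families = [SeedFamily(seed=s, members=sorted(names)) for s, names in by_seed.items()]

    if smallrna_counts is not None:
        missing = set(smallrna_counts.index) - known
        if missing:
            log.warning("excluding %d miRNAs present in counts but not in FASTA: %s",
                        len(missing), sorted(missing)[:10])
        mat = cpm(smallrna_counts.loc[[i for i in smallrna_counts.index if i in known]])
        cols = mat.columns
        if use_condition is not None:
            if condition is None:
                raise ValueError("use_condition given without a condition map")
            cols = [c for c in mat.columns if condition[c] == use_condition]
        for fam in families:
            present = [m for m in fam.members if m in mat.index]
            fam.expression_cpm = mat.loc[present].sum(axis=0)
        families.sort(key=lambda f: (-f.expression_cpm[cols].mean(), f.seed))
    else:
        families.sort(key=lambda f: f.seed)
    for r, fam in enumerate(families, 1):
        fam.rank = r
    if top_k is not None:
        families = families[:top_k]
    return families


def _region_of(peak_start: int, peak_end: int, gene: GeneModel) -> str:
    """Region label by maximal overlap among 3'UTR, CDS (exon minus UTR), intron."""

    def ov(a, b):
        return max(0, min(peak_end, b) - max(peak_start, a))

    utr = ov(*gene.utr3) if gene.utr3 else 0
    exonic = sum(ov(s, e) for s, e in gene.exons)
    cds = exonic - utr
    intron = sum(ov(s, e) for s, e in gene.introns)
    other = (peak_end - peak_start) - exonic - intron
    # priority on ties: the most specific annotation wins
    best = max(
        [(utr, 0, "3'UTR"), (cds, 1, "CDS"), (intron, 2, "intron"), (other, 3, "other")],
        key=lambda t: (t[0], -t[1]),
    )
    return best[2]


def genome_to_utr(peak_start: int, peak_end: int, gene: GeneModel) -> tuple[int, int]:
    """Map a genome interval (clipped to the 3'UTR) into UTR 5'->3' offsets."""
    s, e = gene.utr3
    ps, pe = max(peak_start, s), min(peak_end, e)
    if ps >= pe:
        raise ValueError("peak does not overlap the 3'UTR")
    if gene.strand == "+":
        return ps - s, pe - s
    return e - pe, e - ps


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    utr_seqs: dict[str, str],
    families: list[SeedFamily],
) -> list[EclipPeak]:
    """Assign region labels and seed sites to eCLIP peaks.

    ``peaks`` is a BED6+compartment frame (see :mod:`mirisc_shift.io`);
    peak->gene assignment is by the ``name`` column. Site scanning is
    restricted to the peak footprint within the 3'UTR, strand-aware. Peaks
    naming unannotated genes are skipped with a log message.
    """
    by_id = {g.gene_id: g for g in genes}
    out: list[EclipPeak] = []
    for row in peaks.itertuples(index=False):
        gene = by_id.get(row.name)
        if gene is None:
            log.warning("peak %s:%d-%d names unannotated gene %s; skipped",
                        row.chrom, row.start, row.end, row.name)
            continue
        comp = {"cyto": "cytoplasm", "nuc": "nucleus"}.get(row.compartment, row.compartment)
        pk = EclipPeak(row.chrom, int(row.start), int(row.end), gene.gene_id, gene.strand, comp)
        pk.region = _region_of(pk.start, pk.end, gene)
        if gene.utr3 and pk.region == "3'UTR":
            us, ue = genome_to_utr(pk.start, pk.end, gene)
            utr = utr_seqs[gene.gene_id]
            for fam in families:
                for site in sites_for_seed(utr, fam.seed, utr_id=gene.gene_id):
                    if site.start >= us and site.end <= ue:
                        pk.sites.append(site)
        out.append(pk)
    return out


def utr_site_peak_counts(annotated: list[EclipPeak], site_types=SITE_TYPES) -> pd.Series:
    """Per-gene tally of cytoplasmic 3'UTR peaks with >=1 qualifying site."""
    counts: dict[str, int] = {}
    for pk in annotated:
        if pk.compartment != "cytoplasm" or pk.region != "3'UTR":
            continue
        if any(s.site_type in site_types for s in pk.sites):
            counts[pk.gene_id] = counts.get(pk.gene_id, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def sites_table(annotated: list[EclipPeak]) -> pd.DataFrame:
    """Flat TSV-ready table of all sites in annotated peaks."""
    rows = []
    for pk in annotated:
        for s in pk.sites:
            rows.append(
                dict(gene=pk.gene_id, peak=f"{pk.chrom}:{pk.start}-{pk.end}",
                     compartment=pk.compartment, region=pk.region,
                     offset=s.start, type=s.site_type, family_seed=s.family_seed)
            )
    return pd.DataFrame(rows, columns=["gene", "peak", "compartment", "region",
                                       "offset", "type", "family_seed"])
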