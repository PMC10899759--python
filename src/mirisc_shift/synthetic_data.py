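"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design end to end: a compact annotated
genome of non-overlapping multi-exon genes with 3'UTRs, a mirnome organized
into seed families with power-law abundances (the most abundant few families
dominating the read pool), two-condition (low/high density) x 3-replicate NB
count matrices with separately planted transcriptional and
post-transcriptional log2 effects, AGO2-eCLIP-style 3'UTR peaks carrying
planted 7mer/8mer seed-match sites plus decoys, exponential-decay Ct series
over the 0-48 h actinomycin-D grid with stable reference genes, and linear
densitometry dilution series for absolute protein quantification.

All randomness flows from ``SimConfig.rng_seed`` through fixed per-stage
sub-streams, so identical configurations produce byte-identical output
files regardless of the order stages are invoked.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .decay_qpcr import REFERENCE_GENES, TIMEPOINTS_H
from .io import GeneModel
from .quantitation import Avogadro
from .seedmatch import SITE_TYPES, normalize_dna, revcomp_dna, sites_for_seed

CONDITIONS = ("low_density", "high_density")
FRACTIONS = ("cytoplasm", "nucleus")

# fixed per-stage RNG sub-stream offsets
_STAGES = {"annotation": 0, "mirnome": 1, "plant": 2, "peaks": 3, "counts": 4,
           "decay": 5, "densitometry": 6}


def _default_halflives() -> dict:
    # cytoplasmic stabilization at high density; nuclear stability unchanged
    per_gene = {
        "cytoplasm": {"low_density": 6.0, "high_density": 12.0},
        "nucleus": {"low_density": 8.0, "high_density": 8.0},
    }
    return {g: {f: dict(c) for f, c in per_gene.items()} for g in ("TARGET1", "TARGET2", "TARGET3")}


def _default_copies() -> dict:
    # whole-cell totals and nuclear:cytoplasmic splits of 2:1 (low) and 12:1 (high)
    return {
        "low_density": {"whole_cell": 70_000.0, "nucleus": 70_000.0 * 2 / 3,
                        "cytoplasm": 70_000.0 / 3},
        "high_density": {"whole_cell": 88_000.0, "nucleus": 88_000.0 * 12 / 13,
                         "cytoplasm": 88_000.0 / 13},
    }


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic data generator."""

    n_genes: int = 500
    n_mirnas: int = 60
    n_families: int = 25
    n_replicates: int = 3
    library_size: int = 2_000_000
    nb_dispersion: float = 0.05          # var = mu + phi mu^2
    frac_candidates: float = 0.05
    tx_effect_log2: float = 0.5
    ptx_effect_log2: float = 1.5
    mirna_global_log2fc: float = 0.8     # ~1.74-fold global shift at high density
    decay_halflives_h: dict = field(default_factory=_default_halflives)
    ct_noise_sd: float = 0.2
    rng_seed: int = 0

    # gene architecture
    utr_length: int = 600
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (200, 800)
    n_exons_range: tuple[int, int] = (2, 4)
    intergenic_gap_range: tuple[int, int] = (200, 500)

    # eCLIP peaks
    peak_length: int = 50
    max_peaks_per_candidate: int = 3
    planted_top_families: int = 10       # plant sites only for the top ranks
    decoy_utr_peak_prob: float = 0.3
    decoy_intron_peak_prob: float = 0.2

    # expression profile
    abundance_sigma: float = 1.0         # lognormal spread of gene abundances
    family_abundance_exponent: float = 1.1

    # decay assay
    arrest_halflife_h: float = 0.5       # pre-mRNA decay after actinomycin D

    # densitometry
    standard_masses_ng: tuple[float, ...] = (25.0, 12.5, 6.25, 3.125, 1.5625, 0.78125, 0.390625)
    densitometry_slope: float = 1000.0   # intensity a.u. per ng
    densitometry_intercept: float = 0.0
    densitometry_noise_sd: float = 0.0
    cells_per_ul: float = 10_000.0
    loaded_volume_ul: float = 10.0
    protein_molar_mass: float = 97_000.0
    true_copies: dict = field(default_factory=_default_copies)

    def __post_init__(self):
        if self.n_genes < 0 or self.n_mirnas <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if self.n_mirnas < self.n_families:
            raise ValueError("n_mirnas must be >= n_families")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.frac_candidates <= 1:
            raise ValueError("frac_candidates must be in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.peak_length > self.utr_length:
            raise ValueError("peak_length exceeds utr_length")
        for gene, fracs in self.decay_halflives_h.items():
            for frac, conds in fracs.items():
                for cond, th in conds.items():
                    if not th > 0:
                        raise ValueError(f"half-life for {gene}/{frac}/{cond} must be > 0")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, _STAGES[stage]])


@dataclass
class Annotation:
    genes: list[GeneModel]
    genome: dict[str, str]

    def utr_seqs(self) -> dict[str, str]:
        return {g.gene_id: g.utr_sequence(self.genome) for g in self.genes if g.utr3}


@dataclass
class GroundTruth:
    """Everything the downstream stages should be able to re-derive."""

    family_members: dict[str, list[str]] = field(default_factory=dict)   # seed -> names
    family_abundance: dict[str, float] = field(default_factory=dict)     # seed -> rel. abundance
    mirna_abundance: dict[str, float] = field(default_factory=dict)
    top_family_seeds: list[str] = field(default_factory=list)            # ranked
    candidate_gene_ids: list[str] = field(default_factory=list)
    tx_effects_log2: dict[str, float] = field(default_factory=dict)
    ptx_effects_log2: dict[str, float] = field(default_factory=dict)
    planted_peaks: dict[str, list[dict]] = field(default_factory=dict)   # gene -> peaks
    true_halflives_h: dict = field(default_factory=dict)
    true_copies_per_cell: dict = field(default_factory=dict)
    planted: bool = False

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimConfig) -> Annotation:
    """Non-overlapping multi-exon genes with 3'UTRs on one synthetic chromosome.

    Every gene has >=2 exons (so introns exist); the 3'UTR occupies the
    terminal ``utr_length`` of the last exon in transcript orientation.
    """
    if cfg.n_genes == 0:
        raise ValueError("n_genes is 0: empty annotation")
    rng = cfg.rng("annotation")
    chrom = "chr1"
    pos = int(rng.integers(*cfg.intergenic_gap_range))
    genes: list[GeneModel] = []
    chunks: list[str] = ["".join(rng.choice(list("ACGT"), size=pos))]
    for i in range(cfg.n_genes):
        gene_id = f"G{i+1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exon_lens = rng.integers(*cfg.exon_length_range, size=n_ex).tolist()
        # terminal exon must contain the full UTR
        term = 0 if strand == "-" else n_ex - 1
        exon_lens[term] = cfg.utr_length + int(rng.integers(100, 200))
        intron_lens = rng.integers(*cfg.intron_length_range, size=n_ex - 1).tolist()
        exons = []
        p = pos
        for j, el in enumerate(exon_lens):
            exons.append((p, p + el))
            p += el
            if j < n_ex - 1:
                p += intron_lens[j]
        if strand == "+":
            s, e = exons[-1]
            utr3 = (e - cfg.utr_length, e)
        else:
            s, e = exons[0]
            utr3 = (s, s + cfg.utr_length)
        gene_len = p - pos
        chunks.append("".join(rng.choice(list("ACGT"), size=gene_len)))
        genes.append(GeneModel(gene_id, chrom, pos, p, strand, exons, utr3))
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        chunks.append("".join(rng.choice(list("ACGT"), size=gap)))
        pos = p + gap
    return Annotation(genes=genes, genome={chrom: "".join(chunks)})


# ---------------------------------------------------------------------------
# mirnome


def simulate_mirnome(cfg: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Mature miRNA sequences grouped into seed families, plus ground truth.

    Families share nt 2-8 exactly; distinct families have distinct seeds.
    Family abundances follow a power law in rank (the top families dominate
    the read pool, as in real small-RNA libraries).
    """
    rng = cfg.rng("mirnome")
    seeds: list[str] = []
    seen = set()
    while len(seeds) < cfg.n_families:
        s = "".join(rng.choice(list("ACGU"), size=7))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    # one member per family first, remainder assigned randomly
    assignment = list(range(cfg.n_families))
    assignment += rng.integers(0, cfg.n_families, size=cfg.n_mirnas - cfg.n_families).tolist()

    truth = GroundTruth()
    fam_rel = np.arange(1, cfg.n_families + 1, dtype=float) ** (-cfg.family_abundance_exponent)
    fam_rel /= fam_rel.sum()
    mirnas: dict[str, str] = {}
    member_weights: dict[str, list[float]] = {s: [] for s in seeds}
    for i, fam_idx in enumerate(assignment):
        seed = seeds[fam_idx]
        length = int(rng.integers(20, 25))
        first = rng.choice(list("ACGU"))
        tail = "".join(rng.choice(list("ACGU"), size=length - 8))
        name = f"miR-{i+1:03d}"
        mirnas[name] = first + seed + tail
        truth.family_members.setdefault(seed, []).append(name)
        member_weights[seed].append(float(rng.uniform(0.2, 1.0)))
    for fam_idx, seed in enumerate(seeds):
        truth.family_abundance[seed] = float(fam_rel[fam_idx])
        w = np.array(member_weights[seed])
        w /= w.sum()
        for name, frac in zip(truth.family_members[seed], w):
            truth.mirna_abundance[name] = float(fam_rel[fam_idx] * frac)
    ranked = sorted(truth.family_abundance, key=lambda s: (-truth.family_abundance[s], s))
    truth.top_family_seeds = ranked
    truth.true_halflives_h = cfg.decay_halflives_h
    truth.true_copies_per_cell = cfg.true_copies
    return mirnas, truth


# ---------------------------------------------------------------------------
# planting candidates and peak blueprints


def plant_candidates(cfg: SimConfig, annotation: Annotation, truth: GroundTruth) -> GroundTruth:
    """Choose candidate genes, their effects, and peak/site blueprints."""
    rng = cfg.rng("plant")
    n_cand = int(round(cfg.frac_candidates * len(annotation.genes)))
    ids = [g.gene_id for g in annotation.genes]
    cand = sorted(rng.choice(ids, size=n_cand, replace=False).tolist())
    truth.candidate_gene_ids = cand
    truth.tx_effects_log2 = {g: (cfg.tx_effect_log2 if g in cand else 0.0) for g in ids}
    truth.ptx_effects_log2 = {g: (cfg.ptx_effect_log2 if g in cand else 0.0) for g in ids}

    top = truth.top_family_seeds[: cfg.planted_top_families]
    by_id = {g.gene_id: g for g in annotation.genes}
    pk_len = cfg.peak_length
    for gid in cand:
        gene = by_id[gid]
        utr_len = gene.utr3[1] - gene.utr3[0]
        kmax = min(cfg.max_peaks_per_candidate, utr_len // pk_len)
        k = int(rng.integers(1, kmax + 1))
        block = utr_len // k
        peaks = []
        for j in range(k):
            lo = j * block
            start = int(rng.integers(lo, lo + block - pk_len + 1))
            seed = str(rng.choice(top))
            site_type = str(rng.choice(SITE_TYPES))
            motif_len = 8 if site_type == "8mer" else 7
            # keep one guard base on each side of the site inside the peak
            site_off = int(rng.integers(start + 1, start + pk_len - motif_len))
            peaks.append(
                dict(utr_start=start, utr_end=start + pk_len, seed=seed,
                     site_type=site_type, site_utr_offset=site_off)
            )
        truth.planted_peaks[gid] = peaks
    truth.planted = True
    return truth


# ---------------------------------------------------------------------------
# eCLIP peaks (and genome editing to embed the sites)


def _write_utr(genome: dict[str, str], gene: GeneModel, utr_off: int, motif: str) -> None:
    """Write ``motif`` (DNA, UTR 5'->3' frame) into the genome, strand-aware."""
    chrom = genome[gene.chrom]
    s, e = gene.utr3
    if gene.strand == "+":
        gpos = s + utr_off
        genome[gene.chrom] = chrom[:gpos] + motif + chrom[gpos + len(motif):]
    else:
        gend = e - utr_off
        rc = revcomp_dna(normalize_dna(motif))
        genome[gene.chrom] = chrom[: gend - len(motif)] + rc + chrom[gend:]


def _plant_site(genome: dict[str, str], gene: GeneModel, seed_rna: str, site_type: str,
                utr_off: int) -> None:
    seed_dna = normalize_dna(seed_rna)
    m8 = revcomp_dna(seed_dna)
    if site_type == "8mer":
        motif = m8 + "A"
    elif site_type == "7mer-m8":
        motif = m8 + "C"           # guard: no trailing A, else it becomes an 8mer
    elif site_type == "7mer-A1":
        guard = "C" if seed_dna[6] != "G" else "T"   # not complement(nt8)
        motif = guard + revcomp_dna(seed_dna[:6]) + "A"
        utr_off -= 1
    else:
        raise ValueError(f"unknown site type {site_type}")
    _write_utr(genome, gene, utr_off, motif)


def _scrub_peak(genome: dict[str, str], gene: GeneModel, utr_start: int, utr_end: int,
                all_seeds: list[str], rng: np.random.Generator) -> None:
    """Rewrite a decoy peak footprint until it contains no seed-match site."""
    for _ in range(100):
        utr = gene.utr_sequence(genome)
        hits = [
            site
            for seed in all_seeds
            for site in sites_for_seed(utr, seed)
            if site.start >= utr_start and site.end <= utr_end
        ]
        if not hits:
            return
        fresh = "".join(rng.choice(list("ACGT"), size=utr_end - utr_start))
        _write_utr(genome, gene, utr_start, fresh)
    raise RuntimeError("could not scrub decoy peak of seed matches")


def simulate_eclip_peaks(cfg: SimConfig, annotation: Annotation, truth: GroundTruth
                         ) -> pd.DataFrame:
    """BED6+compartment peaks; edits the genome to embed planted sites.

    Candidate genes get 1..k cytoplasmic 3'UTR peaks, each carrying one
    planted top-family site, plus one nuclear 3'UTR decoy with a site
    (exercises the compartment filter). Non-candidates receive site-free
    cytoplasmic 3'UTR decoys and intronic decoys.
    """
    if not truth.planted:
        raise ValueError("ground truth has no planted candidates; run plant_candidates first")
    if cfg.peak_length > cfg.utr_length:
        raise ValueError("peak longer than UTR")
    rng = cfg.rng("peaks")
    by_id = {g.gene_id: g for g in annotation.genes}
    all_seeds = sorted(truth.family_abundance)
    rows = []

    def genome_interval(gene: GeneModel, utr_s: int, utr_e: int) -> tuple[int, int]:
        s, e = gene.utr3
        if gene.strand == "+":
            return s + utr_s, s + utr_e
        return e - utr_e, e - utr_s

    for gid, peaks in sorted(truth.planted_peaks.items()):
        gene = by_id[gid]
        for pk in peaks:
            _plant_site(annotation.genome, gene, pk["seed"], pk["site_type"],
                        pk["site_utr_offset"])
            gs, ge = genome_interval(gene, pk["utr_start"], pk["utr_end"])
            rows.append((gene.chrom, gs, ge, gid, 0, gene.strand, "cyto"))
        # nuclear decoy with a real site: compartment filter must exclude it;
        # placed clear of the planted cytoplasmic peaks
        taken = [(pk["utr_start"], pk["utr_end"]) for pk in peaks]
        start = None
        for _ in range(50):
            cand_start = int(rng.integers(0, cfg.utr_length - cfg.peak_length + 1))
            if all(cand_start + cfg.peak_length <= s or cand_start >= e for s, e in taken):
                start = cand_start
                break
        if start is None:
            continue
        seed = str(rng.choice(truth.top_family_seeds[: cfg.planted_top_families]))
        off = int(rng.integers(start + 1, start + cfg.peak_length - 8))
        _plant_site(annotation.genome, gene, seed, "8mer", off)
        gs, ge = genome_interval(gene, start, start + cfg.peak_length)
        rows.append((gene.chrom, gs, ge, gid, 0, gene.strand, "nuc"))

    cand = set(truth.candidate_gene_ids)
    for gene in annotation.genes:
        if gene.gene_id in cand:
            continue
        if rng.random() < cfg.decoy_utr_peak_prob:
            start = int(rng.integers(0, cfg.utr_length - cfg.peak_length + 1))
            _scrub_peak(annotation.genome, gene, start, start + cfg.peak_length, all_seeds, rng)
            gs, ge = genome_interval(gene, start, start + cfg.peak_length)
            rows.append((gene.chrom, gs, ge, gene.gene_id, 0, gene.strand, "cyto"))
        if rng.random() < cfg.decoy_intron_peak_prob and gene.introns:
            i_s, i_e = gene.introns[0]
            if i_e - i_s > cfg.peak_length:
                start = int(rng.integers(i_s, i_e - cfg.peak_length))
                rows.append((gene.chrom, start, start + cfg.peak_length, gene.gene_id, 0,
                             gene.strand, "cyto"))
    df = pd.DataFrame(rows, columns=io.BED_COLUMNS)
    return df.sort_values(["chrom", "start", "end", "compartment"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.clip(mu, 1e-12, None)
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def sample_names(cfg: SimConfig) -> list[str]:
    return [f"{cond}_rep{i+1}" for cond in CONDITIONS for i in range(cfg.n_replicates)]


def design(cfg: SimConfig) -> pd.Series:
    names = sample_names(cfg)
    return pd.Series([n.rsplit("_rep", 1)[0] for n in names], index=pd.Index(names, name="sample"),
                     name="condition")


def simulate_counts(cfg: SimConfig, annotation: Annotation, truth: GroundTruth
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Exonic, intronic and small-RNA NB count matrices.

    Candidate genes at high density have intronic means scaled by
    2^tx_effect and exonic means by 2^(tx_effect + ptx_effect); every miRNA
    shifts by 2^mirna_global_log2fc. Expected column sums equal
    ``library_size`` in the low-density baseline.
    """
    if not truth.planted:
        raise ValueError("ground truth has no planted candidates; run plant_candidates first")
    rng = cfg.rng("counts")
    ids = [g.gene_id for g in annotation.genes]
    rel = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=len(ids))
    rel /= rel.sum()
    base = rel * cfg.library_size
    tx = np.array([truth.tx_effects_log2[g] for g in ids])
    ptx = np.array([truth.ptx_effects_log2[g] for g in ids])

    cols = sample_names(cfg)
    ex = np.zeros((len(ids), len(cols)), dtype=np.int64)
    it = np.zeros_like(ex)
    for j, name in enumerate(cols):
        high = name.startswith("high_density")
        mu_ex = base * (2.0 ** (tx + ptx) if high else 1.0)
        mu_it = base * (2.0 ** tx if high else 1.0)
        ex[:, j] = _nb_draw(rng, mu_ex, cfg.nb_dispersion)
        it[:, j] = _nb_draw(rng, mu_it, cfg.nb_dispersion)

    mir_names = sorted(truth.mirna_abundance)
    mir_rel = np.array([truth.mirna_abundance[m] for m in mir_names])
    mir_base = mir_rel * cfg.library_size
    sm = np.zeros((len(mir_names), len(cols)), dtype=np.int64)
    for j, name in enumerate(cols):
        shift = 2.0**cfg.mirna_global_log2fc if name.startswith("high_density") else 1.0
        sm[:, j] = _nb_draw(rng, mir_base * shift, cfg.nb_dispersion)

    gidx = pd.Index(ids, name="gene_id")
    midx = pd.Index(mir_names, name="gene_id")
    return (
        pd.DataFrame(ex, index=gidx, columns=cols),
        pd.DataFrame(it, index=gidx, columns=cols),
        pd.DataFrame(sm, index=midx, columns=cols),
    )


# ---------------------------------------------------------------------------
# decay Ct series


def simulate_decay(cfg: SimConfig) -> pd.DataFrame:
    """Ct table over the actinomycin-D time course.

    Target Ct(t) = Ct(0) + t/t_half + noise (one Ct unit per halving);
    reference genes are constant in expectation; nuclear pre-mRNA rows
    (``pre_<gene>``) decay with ``arrest_halflife_h`` to document arrest.
    """
    rng = cfg.rng("decay")
    rows = []
    base_ct = {g: float(rng.uniform(18, 26)) for g in sorted(cfg.decay_halflives_h)}
    ref_ct = {g: 20.0 + 2.0 * i for i, g in enumerate(REFERENCE_GENES)}

    def emit(gene, frac, cond, t_half):
        if not t_half > 0:
            raise ValueError(f"half-life must be > 0 for {gene}")
        for t in TIMEPOINTS_H:
            for rep in range(1, cfg.n_replicates + 1):
                ct = base_ct.get(gene, 24.0) + t / t_half + rng.normal(0, cfg.ct_noise_sd)
                # undetectable transcripts report the instrument ceiling
                rows.append((gene, frac, cond, t, rep, min(float(ct), 40.0)))

    for gene in sorted(cfg.decay_halflives_h):
        for frac in sorted(cfg.decay_halflives_h[gene]):
            for cond in sorted(cfg.decay_halflives_h[gene][frac]):
                emit(gene, frac, cond, cfg.decay_halflives_h[gene][frac][cond])
    for gene in sorted(cfg.decay_halflives_h):
        base_ct[f"pre_{gene}"] = base_ct[gene] + 4.0
        for cond in CONDITIONS:
            emit(f"pre_{gene}", "nucleus", cond, cfg.arrest_halflife_h)
    # stable reference genes in every stratum
    for ref in REFERENCE_GENES:
        for frac in FRACTIONS:
            for cond in CONDITIONS:
                for t in TIMEPOINTS_H:
                    for rep in range(1, cfg.n_replicates + 1):
                        ct = ref_ct[ref] + rng.normal(0, cfg.ct_noise_sd)
                        rows.append((ref, frac, cond, t, rep, round(float(ct), 4)))
    return pd.DataFrame(rows, columns=["gene", "fraction", "condition", "timepoint_h",
                                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# densitometry


def simulate_densitometry(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard-curve dilution series and fraction lane intensities."""
    rng = cfg.rng("densitometry")
    std_rows = []
    for mass in cfg.standard_masses_ng:
        for rep in range(1, 4):
            inten = (cfg.densitometry_slope * mass + cfg.densitometry_intercept
                     + rng.normal(0, cfg.densitometry_noise_sd))
            std_rows.append((mass, rep, float(inten)))
    standards = pd.DataFrame(std_rows, columns=["mass_ng", "replicate", "intensity_au"])

    sample_rows = []
    n_cells = cfg.cells_per_ul * cfg.loaded_volume_ul
    for cond in CONDITIONS:
        for frac in ("whole_cell", "cytoplasm", "nucleus"):
            copies = cfg.true_copies[cond][frac]
            mass_ng = copies * n_cells / Avogadro * cfg.protein_molar_mass * 1e9
            inten = (cfg.densitometry_slope * mass_ng + cfg.densitometry_intercept
                     + rng.normal(0, cfg.densitometry_noise_sd))
            sample_rows.append((frac, cond, float(inten), cfg.loaded_volume_ul,
                                cfg.cells_per_ul))
    samples = pd.DataFrame(
        sample_rows,
        columns=["fraction", "condition", "intensity_au", "loaded_volume_ul", "cells_per_ul"],
    )
    return standards, samples


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedData:
    cfg: SimConfig
    annotation: Annotation
    mirnas: dict[str, str]
    truth: GroundTruth
    peaks: pd.DataFrame
    exonic: pd.DataFrame
    intronic: pd.DataFrame
    smallrna: pd.DataFrame
    ct: pd.DataFrame
    standards: pd.DataFrame
    samples: pd.DataFrame


def simulate_all(cfg: SimConfig) -> SimulatedData:
    annotation = simulate_annotation(cfg)
    mirnas, truth = simulate_mirnome(cfg)
    plant_candidates(cfg, annotation, truth)
    peaks = simulate_eclip_peaks(cfg, annotation, truth)  # edits the genome
    exonic, intronic, smallrna = simulate_counts(cfg, annotation, truth)
    ct = simulate_decay(cfg)
    standards, samples = simulate_densitometry(cfg)
    return SimulatedData(cfg, annotation, mirnas, truth, peaks, exonic, intronic,
                         smallrna, ct, standards, samples)


def write_all(data: SimulatedData, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every simulated input as plain text; returns name -> path."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "genome": os.path.join(outdir, "genome.fa"),
        "utrs": os.path.join(outdir, "utrs.fa"),
        "mirnas": os.path.join(outdir, "mirnas.fa"),
        "peaks": os.path.join(outdir, "peaks.bed"),
        "exonic": os.path.join(outdir, "exonic_counts.tsv"),
        "intronic": os.path.join(outdir, "intronic_counts.tsv"),
        "smallrna": os.path.join(outdir, "smallrna_counts.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
        "ct": os.path.join(outdir, "ct.tsv"),
        "standards": os.path.join(outdir, "densitometry_standards.tsv"),
        "samples": os.path.join(outdir, "densitometry_samples.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    io.write_gff3(paths["annotation"], data.annotation.genes)
    io.write_fasta(paths["genome"], data.annotation.genome)
    io.write_fasta(paths["utrs"], data.annotation.utr_seqs())
    io.write_fasta(paths["mirnas"], data.mirnas)
    io.write_bed(paths["peaks"], data.peaks)
    io.write_counts(paths["exonic"], data.exonic)
    io.write_counts(paths["intronic"], data.intronic)
    io.write_counts(paths["smallrna"], data.smallrna)
    io.write_design(paths["design"], design(data.cfg))
    io.write_table(paths["ct"], data.ct)
    io.write_table(paths["standards"], data.standards)
    io.write_table(paths["samples"], data.samples)
    data.truth.to_json(paths["truth"])
    return paths
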