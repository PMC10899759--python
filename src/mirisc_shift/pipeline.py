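"""End-to-end candidate-refinement pipeline.

Integrates eCLIP peak annotation, seed-family ranking, differential
expression, EISA, half-life estimation and absolute protein quantification
into one run that emits a ranked candidate table, per-stage TSVs, a JSON
provenance block and a plain-text report. A candidate miRISC target is a
gene with at least one cytoplasmic 3'UTR AGO2 peak containing a strong
(8mer/7mer-m8/7mer-A1) seed match to one of the top-k most abundant miRNA
families.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .decay_qpcr import (REFERENCE_GENES, HalfLife, check_transcription_arrest,
                         fit_halflives, relative_abundance)
from .eisa import classify_regulation, eisa
from .expression import nb_exact_test, tmm_factors
from .quantitation import compartment_ratio, copies_per_cell, fit_standard_curve
from .seedmatch import (SITE_TYPES, EclipPeak, Mirna, annotate_peaks, group_families,
                        sites_table)
from .synthetic_data import CONDITIONS, SimConfig, simulate_all, write_all

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, filters and input locations for a pipeline run."""

    outdir: str = "mirisc_run"
    simulate: bool = True
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    inputs: dict = field(default_factory=dict)   # name -> path (when simulate=False)
    top_k_families: int = 20
    de_fdr: float = 0.05
    eisa_fdr: float = 0.001
    eisa_min_log2_mean: float = 5.0
    site_types: tuple = SITE_TYPES
    compartment: str = "cytoplasm"
    region: str = "3'UTR"
    rng_seed: int = 0

    def __post_init__(self):
        for name, v in (("de_fdr", self.de_fdr), ("eisa_fdr", self.eisa_fdr)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        self.site_types = tuple(self.site_types)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def refine_candidates(
    annotated: list[EclipPeak],
    top_families: list,
    de: pd.DataFrame,
    *,
    site_types=SITE_TYPES,
    de_fdr: float = 0.05,
    compartment: str = "cytoplasm",
    region: str = "3'UTR",
) -> pd.DataFrame:
    """Ranked candidate targets passing the peak + seed-site filter.

    Keeps genes with >=1 peak in ``compartment``/``region`` containing >=1
    site of an allowed type for a top-family seed, annotates differential
    expression, and flags the upregulated subset (log2FC > 0, FDR <
    ``de_fdr``). Rank is a total order: site count desc, log2FC desc, gene id.
    """
    top_seeds = {f.seed for f in top_families}
    per_gene: dict[str, dict] = {}
    peak_genes = set()
    for pk in annotated:
        peak_genes.add(pk.gene_id)
        if pk.compartment != compartment or pk.region != region:
            continue
        qual = {s.family_seed for s in pk.sites
                if s.site_type in site_types and s.family_seed in top_seeds}
        if not qual:
            continue
        entry = per_gene.setdefault(pk.gene_id, {"n_utr_sites": 0, "families": set()})
        entry["n_utr_sites"] += 1
        entry["families"] |= qual

    de_idx = de.set_index("gene")
    if peak_genes and len(de_idx) and not (peak_genes & set(de_idx.index)):
        raise ValueError(
            "gene universes do not intersect: peaks name genes like "
            f"{sorted(peak_genes)[:3]} but DE has {list(de_idx.index[:3])}"
        )
    rows = []
    for gid, entry in per_gene.items():
        l2fc = float(de_idx.at[gid, "log2fc"]) if gid in de_idx.index else np.nan
        fdr = float(de_idx.at[gid, "fdr"]) if gid in de_idx.index else np.nan
        rows.append(
            dict(gene=gid, n_utr_sites=entry["n_utr_sites"],
                 families=",".join(sorted(entry["families"])),
                 log2fc=l2fc, de_fdr=fdr,
                 upregulated=bool(l2fc > 0 and fdr < de_fdr))
        )
    out = pd.DataFrame(rows, columns=["gene", "n_utr_sites", "families", "log2fc",
                                      "de_fdr", "upregulated"])
    if len(out):
        out = out.sort_values(["n_utr_sites", "log2fc", "gene"],
                              ascending=[False, False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def attach_eisa(candidates: pd.DataFrame, eisa_classed: pd.DataFrame) -> pd.DataFrame:
    """Left-join EISA class/effects; candidates EISA filtered out are ``untested``."""
    if candidates.empty:
        out = candidates.copy()
        out["eisa_class"] = pd.Series(dtype=str)
        out["d_diff"] = pd.Series(dtype=float)
        return out
    sub = eisa_classed.set_index("gene")[["class", "d_diff", "fdr"]]
    sub.columns = ["eisa_class", "d_diff", "eisa_fdr"]
    out = candidates.merge(sub, left_on="gene", right_index=True, how="left")
    out["eisa_class"] = out["eisa_class"].fillna("untested")
    return out


def _read_inputs(paths: dict) -> dict:
    genes = io.read_gff3(paths["annotation"])
    return dict(
        genes=genes,
        utrs=io.read_fasta(paths["utrs"]),
        mirnas=[Mirna(n, s) for n, s in io.read_fasta(paths["mirnas"]).items()],
        peaks=io.read_bed(paths["peaks"]),
        exonic=io.read_counts(paths["exonic"]),
        intronic=io.read_counts(paths["intronic"]),
        smallrna=io.read_counts(paths["smallrna"]),
        design=io.read_design(paths["design"]),
        ct=io.read_table(paths["ct"]),
        standards=io.read_table(paths["standards"]),
        samples=io.read_table(paths["samples"]),
    )


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``cfg.outdir``.

    Deterministic under a fixed seed: re-running the same configuration
    reproduces byte-identical outputs. Any stage failure aborts with a
    stage-named error and removes the partial output directory.
    """
    outdir = os.path.join(cfg.outdir, "outputs")
    os.makedirs(cfg.outdir, exist_ok=True)
    if os.path.isdir(outdir):
        shutil.rmtree(outdir)
    os.makedirs(outdir)
    stage = "setup"
    timings: dict[str, float] = {}
    report: list[str] = []
    try:
        t0 = time.perf_counter()
        stage = "simulate"
        if cfg.simulate:
            sim_cfg = SimConfig(rng_seed=cfg.rng_seed, **cfg.sim)
            paths = write_all(simulate_all(sim_cfg), os.path.join(cfg.outdir, "inputs"))
        else:
            paths = dict(cfg.inputs)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "read_inputs"
        data = _read_inputs(paths)
        cond = data["design"]
        low, high = CONDITIONS
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "families"
        families = group_families(data["mirnas"], data["smallrna"])
        top = families[: cfg.top_k_families]
        fam_table = pd.DataFrame(
            [dict(seed=f.seed, rank=f.rank, n_members=len(f.members),
                  members=",".join(f.members),
                  mean_cpm=float(f.expression_cpm.mean()) if f.expression_cpm is not None
                  else np.nan)
             for f in families]
        )
        io.write_table(os.path.join(outdir, "families.tsv"), fam_table)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "de"
        factors = tmm_factors(data["exonic"])
        de = nb_exact_test(data["exonic"], factors, cond, low, high)
        io.write_table(os.path.join(outdir, "de.tsv"), de)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "scan"
        annotated = annotate_peaks(data["peaks"], data["genes"], data["utrs"], top)
        io.write_table(os.path.join(outdir, "sites.tsv"), sites_table(annotated))
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "refine"
        candidates = refine_candidates(
            annotated, top, de, site_types=cfg.site_types, de_fdr=cfg.de_fdr,
            compartment=cfg.compartment, region=cfg.region,
        )
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "eisa"
        eisa_res = eisa(data["exonic"], data["intronic"], cond, low, high,
                        min_log2_mean=cfg.eisa_min_log2_mean)
        classed, line = classify_regulation(eisa_res, fdr_threshold=cfg.eisa_fdr)
        io.write_table(os.path.join(outdir, "eisa.tsv"), classed)
        candidates = attach_eisa(candidates, classed)
        io.write_table(os.path.join(outdir, "candidates.tsv"), candidates)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "halflife"
        rel = relative_abundance(data["ct"], REFERENCE_GENES)
        hl = fit_halflives(rel)
        comp_rows = []
        for (gene, frac), sub in hl.groupby(["gene", "fraction"]):
            if gene.startswith("pre_"):
                continue
            by_cond = {r.condition: r for r in sub.itertuples()}
            if low in by_cond and high in by_cond:
                a, b = by_cond[low], by_cond[high]
                ratio = (b.t_half_h / a.t_half_h
                         if np.isfinite(a.t_half_h) and np.isfinite(b.t_half_h) else np.nan)
                comp_rows.append(dict(gene=gene, fraction=frac, t_half_low_h=a.t_half_h,
                                      t_half_high_h=b.t_half_h, ratio_high_over_low=ratio))
        hl_out = hl.copy()
        io.write_table(os.path.join(outdir, "halflife.tsv"), hl_out)
        io.write_table(os.path.join(outdir, "halflife_comparison.tsv"),
                       pd.DataFrame(comp_rows))
        arrest = check_transcription_arrest(
            rel[rel["gene"].str.startswith("pre_") & (rel["fraction"] == "nucleus")]
        ) if rel["gene"].str.startswith("pre_").any() else {}
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "quant"
        curve = fit_standard_curve(data["standards"]["mass_ng"],
                                   data["standards"]["intensity_au"])
        quant_rows = []
        ratios = {}
        for cond_name, sub in data["samples"].groupby("condition"):
            ests = {}
            for r in sub.itertuples():
                est = copies_per_cell(r.intensity_au, curve, cells_per_ul=r.cells_per_ul,
                                      loaded_volume_ul=r.loaded_volume_ul,
                                      fraction=r.fraction, condition=cond_name)
                ests[r.fraction] = est
                quant_rows.append(dict(fraction=r.fraction, condition=cond_name,
                                       copies_per_cell=est.copies_per_cell,
                                       mass_ng=est.mass_ng, flag=est.flag))
            if "nucleus" in ests and "cytoplasm" in ests:
                ratios[cond_name] = compartment_ratio(
                    ests["nucleus"], ests["cytoplasm"], ests.get("whole_cell"))
        io.write_table(os.path.join(outdir, "quant.tsv"), pd.DataFrame(quant_rows))
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        cfg_dict = dataclasses.asdict(cfg)
        # run location is not part of the scientific configuration
        cfg_dict.pop("outdir", None)
        cfg_dict.pop("inputs", None)
        cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
        provenance = dict(
            config=cfg_dict,
            config_sha256=hashlib.sha256(cfg_json.encode()).hexdigest(),
            seed=cfg.rng_seed,
            version=__version__,
            stages=sorted(timings),
            eisa_fit_line=dict(slope=line[0], intercept=line[1]),
        )
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)

        n_up = int(candidates["upregulated"].sum()) if len(candidates) else 0
        report.append(f"candidate miRISC targets: {len(candidates)} ({n_up} upregulated "
                      f"at FDR<{cfg.de_fdr})")
        if len(candidates):
            topc = candidates.iloc[0]
            report.append(f"top candidate: {topc.gene} with {topc.n_utr_sites} "
                          "cytoplasmic 3'UTR peaks carrying seed sites")
        cls_counts = candidates["eisa_class"].value_counts().to_dict() if len(candidates) else {}
        report.append(f"EISA classes among candidates: {cls_counts}")
        for row in comp_rows:
            report.append(f"half-life {row['gene']} ({row['fraction']}): "
                          f"{row['t_half_low_h']:.2f} h -> {row['t_half_high_h']:.2f} h "
                          f"(ratio {row['ratio_high_over_low']:.2f})")
        for cond_name, r in ratios.items():
            report.append(f"AGO2 nuclear:cytoplasmic ratio ({cond_name}): {r['ratio']:.2f}")
        if arrest:
            report.append(f"transcription arrest check: {arrest}")
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write("\n".join(report) + "\n")
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for name, dt in timings.items():
        log.info("stage %-12s %6.2f s", name, dt)
    return dict(outdir=outdir, candidates=candidates, eisa=classed, de=de,
                halflife=hl, ratios=ratios, report="\n".join(report), timings=timings)
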