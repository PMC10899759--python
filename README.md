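# mirisc-shift

Tools for asking a focused question in miRNA biology: when Argonaute 2
(AGO2) relocates from the cytoplasm to the nucleus — as colorectal cancer
cells do when grown to very high density — are the mRNAs it normally
silences in the cytoplasm de-repressed?

The package is aimed at transcriptomics analysts working with paired
AGO2-eCLIP, small-RNA-seq and whole-transcriptome RNA-seq data plus
supporting wet-lab readouts (actinomycin-D decay qPCR, quantitative western
blots). It implements the full inference chain as a tested, reusable
library with a CLI:

* **seedmatch** — miRNA seed extraction (nt 2–8), seed-family grouping and
  ranking by abundance, and scanning of 3'UTR-restricted eCLIP peaks for
  strong sites (8mer, 7mer-m8, 7mer-A1; Watson–Crick only).
* **expression** — CPM, TMM normalization, and an exact conditional
  negative-binomial test of high- vs low-density expression with
  Benjamini–Hochberg FDR.
* **eisa** — exon–intron split analysis: Δexon and Δintron log2 changes,
  Δdiff = Δexon − Δintron, and a per-gene NB likelihood-ratio test on the
  condition×count-type interaction; genes with FDR < 0.001, Δdiff > 0 and a
  positive residual above the Δexon~Δintron best-fit line are called
  post-transcriptionally regulated.
* **decay_qpcr** — 2^−ΔΔCt relative quantification against reference genes
  (HPRT1, SNRNP200, ZMYM4) and exponential half-life fits, t½ = ln2/k, over
  the 0–48 h actinomycin-D grid.
* **quantitation** — absolute AGO2 copies per cell from recombinant-protein
  standard curves (copies = mass·N_A / (M · cells loaded)),
  nuclear:cytoplasmic ratios, and scratch-assay migration rates.
* **synthetic_data** — a first-class generator that produces every input
  (GFF3, FASTA, BED, count/Ct/densitometry TSVs) with planted ground truth,
  so the whole pipeline is testable end to end with no downloads.
* **pipeline** — candidate refinement integrating all of the above: a
  candidate miRISC target has ≥1 cytoplasmic 3'UTR AGO2 peak containing ≥1
  strong seed site for a top-20 miRNA family, annotated with its DE status,
  EISA class and (optionally) half-life evidence.

## Worked example

Run the demo pipeline (simulates its own inputs, then refines candidates):

```bash
mirisc-shift run --outdir demo --seed 11
```

prints

```
candidate miRISC targets: 25 (25 upregulated at FDR<0.05)
top candidate: G0206 with 3 cytoplasmic 3'UTR peaks carrying seed sites
EISA classes among candidates: {'unclassified': 16, 'post_transcriptional': 8, 'transcriptional': 1}
half-life TARGET1 (cytoplasm): 5.93 h -> 11.82 h (ratio 1.99)
half-life TARGET1 (nucleus): 8.23 h -> 7.81 h (ratio 0.95)
...
AGO2 nuclear:cytoplasmic ratio (high_density): 12.00
AGO2 nuclear:cytoplasmic ratio (low_density): 2.00
transcription arrest check: {'high_density': True, 'low_density': True}
```

Reading the numbers: all 25 genes passing the peak + seed-site filter are
significantly upregulated at high density; a subset is confidently
post-transcriptional by EISA (the rest lack the statistical power that the
FDR < 0.001 rule demands at 3 replicates — see `docs/methods.md`). The
planted cytoplasmic half-life doubling (6 h → 12 h) is recovered while
nuclear stability is unchanged, and the absolute quantification recovers the
planted nuclear:cytoplasmic shift from 2:1 to 12:1 with whole-cell totals of
~70 000 and ~88 000 copies per cell. Per-stage tables (`candidates.tsv`,
`de.tsv`, `eisa.tsv`, `sites.tsv`, `halflife.tsv`, `quant.tsv`), a
provenance block and this report are written under `demo/outputs/`.

Each stage is also available separately (`mirisc-shift simulate | scan |
de | eisa | halflife | quant`), and as plain library functions.

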