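# srcrpipe

Comparative analysis of group-B **scavenger receptor cysteine-rich (SRCR)**
receptor families — CD163A, CD163b, CD163c-α and the ruminant γδ T-cell
co-receptor WC1. These receptors are built from 4–11 tandem SRCR domains
(~78–110 aa, up to eight cysteines forming the disulfide bonds
C1–C4, C2–C7, C3–C8 and C5–C6), a transmembrane segment and a cytoplasmic
tail that in WC1 and CD163c-α carries the tyrosine signalling motif
**Y-(Q/E)-(D/C/E)-(I/L)**.

The package is aimed at molecular evolution and comparative immunology work
where receptors from new genomes must be classified: it segments a receptor
into its SRCR domains, names each domain with the field's letter
nomenclature (a, b, c, d, d′, e, h–n) by phylogenetic placement against
letter-labelled reference domains, and summarizes each protein as an
architecture string such as `m-l-b-c-n-d-e-d'` with a family-type call.

## What it computes

- **Domain detection** — a positional profile over the 78-column group-B
  core, aligned glocally (full profile, free ends in the protein) with
  affine gaps; greedy non-overlapping tiling; per-domain cysteine census
  (domains missing C2/C7 and other atypical patterns are reported, not
  dropped).
- **Alignment** — Needleman–Wunsch with affine gaps (open 10.0, extend 0.10,
  Gonnet-250 matrix) and UPGMA-guided progressive multiple alignment,
  projected onto the 78-column core.
- **Divergence** — uncorrected p-distance `p = n_diff / L` with pairwise
  deletion; bootstrap standard errors over alignment columns, which converge
  to `sqrt(p(1-p)/L)`; optional Poisson (`-ln(1-p)`) and JTT-based
  corrections for tree building.
- **Trees** — Saitou–Nei neighbor joining (deterministic tie-breaks, exact
  on additive matrices) with column-bootstrap clade support; newick I/O with
  support as internal node labels.
- **Nomenclature** — each query domain takes the letter of the smallest
  well-supported clade containing it and reference domains of one letter;
  supported query-only clusters receive fresh letters (o, p, …); an
  interior undesignated domain whose flanking letters pin a unique reference
  context is rescued positionally; `d` vs `d'` mixtures resolve by the
  membrane-proximal convention (d′ is a protein's C-terminal domain).
- **Family calls** — diagnostic letters: `k` ⇒ CD163A-like; `a` ⇒ WC1-like;
  any of `m`/`l`/`n` ⇒ CD163c-α-like; `a` together with `m`/`l`/`n` ⇒
  hybrid.
- **Motifs** — Kyte–Doolittle sliding-window transmembrane calls (or
  user-supplied coordinates), cytoplasmic tail extraction, and scans for
  the WC1-type tetramer and literal motifs such as `YREM`.
- **Synthetic families** — a generator that emits multi-domain receptors
  with full ground truth (coordinates, letters, tree, motifs) calibrated to
  the published divergence structure (within-letter p ≈ 0.09–0.23,
  between-letter ≈ 0.45–0.82), used throughout the test suite.

## Worked example

```bash
srcrpipe simulate --seed 17 --out demo --copies 1
srcrpipe scan --in demo/family.fasta --reference demo/reference.fasta --out demo/domains.tsv
```

Running the full pipeline on that family:

```python
from srcrpipe import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    input_fasta="demo/family.fasta",
    reference_alignment="demo/reference.fasta",
    output_dir="demo/out", seed=7, bootstrap_B=100))
for pid, arch in report["architectures"].items():
    print(pid, arch, report["family_calls"][pid])
```

prints

```
syn1_1 a-b-c-d-e-d-b-c-d-e-d' WC1_like
syn2_1 h-i-j-k-b-c-d-e-d' CD163A_like
syn3_1 m-l-b-c-n-d-e-d' CD163c_alpha_like
```

i.e. the three simulated receptors are re-annotated with exactly the WC1,
CD163A and CD163c-α domain architectures they were generated from, and the
motif report locates each cytoplasmic WC1-type tetramer (for example
`syn2_1` position 825, `YEDI`, region `cytoplasmic`).

The output directory contains the domain table (TSV and GFF3), the trimmed
core alignment, distance matrices with a printed-table-style renderer
(values over parenthesized SEs), the support-annotated newick tree, letter
assignments, architecture strings, the motif report and a JSON run log of
every parameter and seed.

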