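# hypoblocks

Tumor genomes frequently lose DNA methylation not at scattered CpGs but in
large coordinated *hypomethylated blocks* — hundreds of kilobases to
megabases of depressed methylation that preferentially fall in
late-replicating, lamina-associated heterochromatin. `hypoblocks` is a
toolkit for epigenomics analysts studying this phenotype: it calls blocks
from tiled bisulfite methylomes, quantifies which genomic features
concentrate inside them, relates copy-number alteration (CNA) burden to
them, and computes the expression statistics that accompany such studies
(proliferation-normalized methyltransferase expression, in-block expression
variability, chromosomal-instability signature scores, regularized
differential expression). A seeded synthetic-data module generates every
input with planted ground truth, so the whole pipeline is testable without
any external download.

## The core computations

**Block calling.** The genome is cut into fixed tiles (default 5 kb). For
each tile and sample, the tile value is the mean methylation fraction β of
the sample's observed CpGs. Tiles are tested case vs. reference with a
Welch two-sample t on per-sample tile means, with Benjamini–Hochberg FDR
across testable tiles. Tiles with q ≤ 0.05 and Δβ ≤ −0.35 are merged when
≤ 250 kb apart (spanning the gaps), and blocks with < 5 CpGs are dropped.
A delta-only mode supports two-sample-per-group designs, where per-tile
p-values carry little information.

**Spatial enrichment.** For a feature track F and block set B on genome G,

- fold enrichment = (|F ∩ B| / |F|) / (bases(B) / bases(G)), features
  assigned by midpoint;
- projection test: exact binomial p for k of n feature midpoints in B with
  success probability bases(B)/bases(G) — for site-like tracks (TF binding
  sites, peaks);
- Jaccard permutation test: J = |A ∩ B| / |A ∪ B| in base pairs, null by
  relocating each query interval uniformly within its chromosome — for
  span-like tracks (LADs, replication-timing domains).

**CNA.** Per-sample CNA index = fraction of the genome in the union of
gained and lost segments; groups compared by Mann–Whitney U.
Coverage-normalized densities (CNA bp per compartment bp, inside vs.
outside blocks) quantify CNA concentration in blocks.

**Expression.** A regularized (Bayesian) two-sample t shrinks per-gene
variance toward the mean variance of the `window` genes nearest in average
intensity: s²_reg = (ν₀·s²_bg + (n−2)·s²_gene)/(ν₀ + n − 2), with
ν₀ + n − 2 degrees of freedom; ν₀ = 0 recovers the pooled t.
Proliferation-normalized expression is the per-sample log2 ratio of a gene
to a proliferation marker (MKI67, PLK1, BUB1). Per-gene variability is the
median absolute deviation (MAD) across case samples, contrasted between
in-block and out-block genes. The CIN25 chromosomal-instability score is
the mean case-vs-reference log2 fold change over a 25-gene signature
supplied as an input list.

## Worked example

The bundled demo simulates a 20-Mb, 8-sample cohort in which the
hypomethylated group carries ~16% of the genome in planted blocks
(Δβ = −0.40), one track placed at 2× density inside blocks, one uniform
track, CNA at 3× in-block concentration and expression with 2× in-block
noise:

```bash
hypoblocks run --config configs/demo.yaml --outdir demo_out
```

prints (abridged):

```json
{
  "simulate":   {"n_cpgs": 40105, "truth_block_fraction": 0.1597},
  "blocks":     {"n_blocks": 6, "block_bases": 3175000, "pct_genome": 15.875},
  "enrichment": {"tracks": {"tfbs_enriched": {"fold": 1.94, "p": 1.5e-85},
                            "uniform_sites": {"fold": 1.01, "p": 0.857},
                            "lad_like":      {"fold": 1.84, "p": 0.005}}},
  "cna":        {"density_ratio": 2.85, "p": 0.0156}
}
```

Reading the output: the caller recovered the planted ~16% block coverage
(15.9% called); the 2×-planted site track shows fold 1.94 with a vanishing
projection p while the uniform track sits at fold 1.01, p 0.86; and CNA
density is ~2.9× higher inside blocks than outside. The expression section
(not shown) reports significantly lower DNMT/UHRF1-to-MKI67 ratios in the
hypomethylated group, an in-block/out-block MAD contrast at p < 1e-15, and
a CIN25 score near the planted 0.8 shift.

Every stage is also exposed as a standalone command (`call-blocks`,
`call-dmr`, `call-dmc`, `enrich`, `cna`, `expr`, `simulate`) over plain
TSV/BED/JSON files, and as library functions.

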