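# clonotrack

Longitudinal single-cell immune-repertoire analysis for 10x-style 5′
GEX + VDJ experiments.

When PBMCs from the same individual are profiled repeatedly over weeks or
months, each sample yields (i) per-cell transcriptome annotations (cell type,
QC metrics) and (ii) assembled TCR/BCR contigs sharing the same cell
barcodes. `clonotrack` joins the two at the barcode level, tracks clonotypes
across time points, and isolates vaccination-associated clonotypes by
repertoire subtraction. It is aimed at immunologists and computational
biologists analysing longitudinal scVDJ-seq cohorts — and at anyone who
needs a fully verifiable synthetic cohort to test such analyses against.

## What it computes

**Clonotype identity.** Two cells share a clonotype when their productive
chains match. The canonical key is the sorted concatenation of
`chain:V:J:CDR3` segments over a cell's productive chains; the default
scheme (`paired_nt`) matches paired chains at CDR3-nucleotide level, with
`paired_aa` and `single_chain:<CHAIN>` as alternatives. Multiple same-chain
contigs in one cell resolve by highest UMI count.

**Persistence.** For each clonotype, k = number of distinct time points with
≥ 1 cell. k = 1 → *unique* (sporadic); k ≥ 2 → *overlapped* (sustained).
Around a vaccination, clonotypes present in any pre-dose sample are
`ovl_pre`; the rest are `not_pre`, split into `not_pre_unique` and
`not_pre_ovl_k`. Baseline subtraction removes every cell whose key occurs in
the union of the supplied baseline repertoires (for a second vaccine study,
the prior study's whole repertoire is subtracted too), and the survivor set
is asserted disjoint from that union.

**Dynamic clonotypes.** With per-time-point frequencies pᵗ among keyed cells
of the receptor class, fold threshold f (default 2) and minimum support m
(default 3 cells): *increased* iff max later frequency ≥ f·p(first) with
peak count ≥ m; *decreased* symmetrically (including drops to zero).

**Diversity.** Shannon index H = −Σ pᵢ ln pᵢ over clonotype frequencies
(nats, no pseudocount), evenness H/ln(n), V-gene and IGH-isotype usage
matrices, and chain-level unique/overlap ratios.

**Statistics.** Cell filtering uses the standard strict thresholds
(200 < nFeature < 4000, percent.mt < 8). Proportions are compared with
two-sided Welch t tests, marker expression with Wilcoxon rank-sum on
log-normalized counts, both Benjamini–Hochberg adjusted across the tested
family.

**Simulator.** `simulate_cohort` generates cohorts with Dirichlet
individual-specific compositions (lymphocytes 70–90 %, monocytes 10–20 %,
CD4:CD8 ≈ 2:1), power-law clone sizes P(s) ∝ s^(−γ), a persistent
memory-clone pool recurring across time points against fresh naive
clonotypes, and optional vaccination effects (transient monocyte expansion,
induced clonotypes rising after dose 1 and boosted after dose 2, elevated
CD69 in their cells) — together with the planted ground truth.

## Worked example

```python
import clonotrack as ct

cfg = ct.SimConfig(
    seed=3, individuals=[{"id": "H1"}],
    time_points=[-1, 1, 3, 7, 28], cells_per_sample=2000,
    vaccination={"dose_days": [0], "n_induced_clonotypes": 50})
ann, contigs, expr, truth = ct.simulate_cohort(cfg)
cohort = ct.build_cohorts(ann, contigs)["H1"]

res = ct.classify_persistence(cohort)
print(res.cell_fractions.round(3).to_string(index=False))

calls = ct.detect_dynamic_clonotypes(cohort, fold=2.0, min_cells=3)
induced = truth.induced_clonotypes["H1"]
hits = calls.increased & induced
print(f"increased: {len(calls.increased)}  decreased: {len(calls.decreased)}")
print(f"recall: {len(hits)/len(induced):.2f}  precision: {len(hits)/len(calls.increased):.2f}")

h = ct.shannon_index(cohort.samples[0].clonotype_counts, sample_id="H1_d-1")
print(f"Shannon H = {h.shannon:.3f} nats over {h.n_clonotypes} clonotypes "
      f"(evenness {h.evenness:.3f})")
```

Output:

```
 time_point  n_cells_unique  n_cells_overlapped  fraction_unique  fraction_overlapped
         -1             821                 383            0.682                0.318
          1             822                 483            0.630                0.370
          3             767                 766            0.500                0.500
          7             803                 997            0.446                0.554
         28             910                 616            0.596                0.404
increased: 50  decreased: 2
recall: 1.00  precision: 1.00
Shannon H = 6.082 nats over 934 clonotypes (evenness 0.889)
```

The sporadic (unique) cells dominate every time point — most of the
repertoire is single-visit naive clonotypes — while the overlapped fraction
peaks on days 3–7 as the 50 planted vaccine-induced clonotypes expand;
dynamic detection recovers all 50 of them with no false positives among the
flat background clones.

The same pipeline runs from a shell:

```bash
clonotrack validate --config examples/influenza_small.yaml
clonotrack run --config examples/influenza_small.yaml --outdir out/
```

which writes QC reports, composition tables and tests, persistence labels,
post-vaccination classifications, dynamic-call lists, diversity/usage
tables, and a run manifest (config hash, seed, per-file sha256) under
`out/`.

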