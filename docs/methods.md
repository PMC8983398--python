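# Methods

This note records the models and procedures implemented in `clonotrack`,
the parameter defaults and the reasoning behind them, what the synthetic
cohorts do and do not emulate, and the package's known limitations.

## Clonotype identity

A cell's clonotype key is the lexicographically sorted concatenation of
`chain:v_gene:j_gene:cdr3` segments over its productive chains, joined by
`|`. Sorting makes the key independent of contig order; using the CDR3
nucleotide sequence and both chains (`paired_nt`, the default) is the
strictest available definition of "same receptor" and matches the common
vendor behaviour. Because longitudinal persistence claims are only as
trustworthy as the matching rule, the scheme is explicit everywhere:
`paired_aa` relaxes to amino-acid CDR3 (merging synonymous rearrangements),
and `single_chain:<CHAIN>` keys one chain only (used for heavy-chain
overlap and isotype analyses, where chain-level identity is the quantity of
interest). Cells with a single recovered productive chain keep a
single-segment key; it can never equal a paired key, so chain dropout
cannot fabricate persistence. When a cell carries several productive
contigs of one chain, the highest-UMI contig wins, ties broken by the
lexicographically smallest CDR3 nucleotide sequence — fully deterministic.

Barcodes are normalized by stripping a trailing `-<digit>` GEM-well suffix
before joining, because GEX and VDJ pipelines emit the suffix
inconsistently across tool versions.

## Persistence, subtraction, and dynamic calls

Persistence is a pure set computation: k = number of distinct time points
at which a key is observed; `unique` iff k = 1. Post-vaccination classes
partition the post-dose repertoire: membership in the pre-vaccination union
takes precedence (`ovl_pre`) regardless of post-dose recurrence; the
remainder splits by post-dose k into `not_pre_unique` and `not_pre_ovl_k`.
The pre-vaccination union is the union over all baseline-phase samples plus
the vaccination phase's own samples at days ≤ the dose day; a second-study
analysis additionally subtracts the entire first-study repertoire.
Subtraction removes cells, not just keys, and the code asserts on every run
that the surviving key set is disjoint from the subtracted union.

Dynamic-clonotype detection uses frequencies among keyed cells of the
receptor class (so uniform changes in sequencing depth cancel). With fold
threshold f and minimum support m, a clonotype first observed at t₀ is
*increased* when its maximum later frequency is ≥ f times its frequency at
t₀ and its peak cell count is ≥ m; *decreased* symmetrically, with a drop
to zero counting as an arbitrarily large fold. Clonotypes seen at a single
time point are never called. Defaults f = 2, m = 3: a doubling below three
cells is indistinguishable from sampling noise at typical per-sample depths
(hundreds to thousands of keyed cells). A clonotype satisfying both rules
(rise then extinction) is reported as increased only, keeping the two sets
disjoint; the parameters are echoed in every output table. There is no
canonical published rule for this operation, so the rule above is the
package's own definition, chosen to be monotone, scale-invariant and fully
parameterized rather than to reproduce any particular published count.

"Observed at more than three time points" style filters are implemented as
k ≥ t_min (default t_min = 3), with a strict `k > t_min` variant
selectable, since the inclusive reading is ambiguous in common usage.

Top-clonotype rankings order by cell count, then earlier first observation,
then key string — deterministic under any input order.

## Diversity

The Shannon index is computed on clonotype frequencies in natural log with
no pseudocount and no rarefaction: H = −Σ pᵢ ln pᵢ. Raw H confounds
richness with evenness, so H/ln(n) is reported alongside. BCR diversity is
chain-resolved (heavy-chain clonotypes) by default, because heavy-chain
identity is the conventional unit for isotype and V-usage analyses;
paired-key diversity is available through the generic entry point. No
depth matching is applied by default — comparisons across samples of very
different sizes should use the optional seeded fixed-depth resampling
(`subsampled_shannon`), since H estimates rise with sampling depth.

Usage matrices (V genes; IGH isotypes) are frequencies among productive
contigs of the chain; the column set is the union observed across the
cohort, zero-filled, and every non-empty row sums to 1. Contigs without a
C gene are counted as `unassigned` rather than dropped, so isotype rows
remain complete.

## QC and statistics

Cell filtering retains cells with 200 < n_features < 4000 and
percent_mt < 8, all strict inequalities, reproducing the conventional
Seurat-style filter; the report counts removals per criterion and the
filter is idempotent.

Group comparisons of cell-type proportions use the two-sided Welch
(unequal-variance) t test on per-sample proportions — the safer default
when group variances differ — with a paired variant exposed for
within-individual designs. Marker-expression comparisons use the two-sided
Wilcoxon rank-sum test on per-cell log-normalized counts (counts scaled to
10,000 per cell, then log1p; stated explicitly because the marker panel is
small, so totals are panel totals). Multiple testing is corrected with
Benjamini–Hochberg across the tested family (the cell types of one
comparison, or the genes of one panel); identical constant groups are
reported as t = 0, p = 1 rather than NaN.

Fresh-vs-frozen concordance summarizes each condition as per-cell-type
pseudobulk (mean log-normalized expression), then reports each gene's
Pearson r across cell types and each cell type's r across genes. Genes
below r = 0.6 (configurable; no published criterion exists for this step)
or with an undefined r that is not an exact match are flagged
low-concordance. Cross-modality agreement is the Pearson r over matched
(sample, cell type) proportion pairs after an explicit label mapping from
the cytometry panel names to the annotation vocabulary.

## The synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes:

* **Composition.** Per individual, a baseline over 15 detailed PBMC types
  (defaults: lymphocytes 80 %, with T 60 % at CD4:CD8 ≈ 2:1, B 8 %,
  NK 12 %; monocytes 15 %; DC 2 %; platelets 3 %) with per-sample
  Dirichlet(α·baseline) draws, α = 500 by default (per-type day-to-day SD
  of roughly 1–2 percentage points, typical of repeat PBMC sampling).
  Vaccination scales the monocyte components by `monocyte_fold`
  (default 1.5) for `monocyte_response_days` (default 3) after each dose
  before renormalization, so the expected monocyte proportion is
  fold·b/(1+(fold−1)·b).
* **Clone sizes.** Discrete power law P(s) ∝ s^(−γ), γ = 2.5, truncated at
  the sample size — the standard heavy-tailed repertoire assumption, giving
  a top-10 share that is small but visible.
* **Persistence.** Each individual has a pool (default 100 T, 60 B clones)
  of persistent clones with *fixed* intrinsic sizes drawn once from the
  power law. At each time point the persistent cell budget
  (`persistent_fraction`, default 0.3, of each lineage's mass) is filled by
  drawing pool clones in random order at their intrinsic sizes. Fixed sizes
  keep per-clone frequencies flat across time, which is what makes the
  dynamic-call false-positive rate measurable; because the sizes are iid
  power-law draws, the emitted clone-size distribution still recovers γ by
  maximum likelihood. Persistent clones carry memory/effector (or
  class-switched B) cell types; naive-typed cells receive fresh clonotypes
  with globally unique CDR3 nucleotide sequences (10–18 sense codons), so
  sporadic ground truth is exact, not merely improbable.
* **Vaccination.** Induced clonotypes (default 50) are new keys never
  emitted pre-dose. Their per-time-point cell counts follow
  `induced_base_cells` (default 3) times a trajectory multiplier — by
  default 0 before dose 1, then 1→3→5→2 after it, and 5→8→4 after a second
  dose (a rise after dose 1 boosted by dose 2). Induced cells are added on
  top of the per-sample cell budget, since at realistic response sizes they
  would otherwise exhaust the persistent budget. Their CD69
  negative-binomial mean is elevated 4-fold.
* **Assay artefacts.** Whole-cell VDJ dropout (default 10 %), per-contig
  UMI counts 1+Poisson(3), negative-binomial marker counts per major cell
  type, and QC covariates (log-normal n_features, Gamma percent_mt) that
  straddle the filter thresholds.

Everything derives from one integer seed through a single generator
consumed in deterministic order; identical configs give byte-identical
tables.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: V(D)J recombination sequence statistics
(CDR3s are uniform random sense codons), somatic hypermutation and clonal
lineages, transcriptome-wide expression, doublets and ambient
contamination, batch effects between time points, and biological coupling
between composition shifts and specific clonotype expansions beyond the
planted mechanisms. Recovery results on simulated cohorts demonstrate the
correctness of the set operations and the detectability of effects of the
planted size, not performance on real repertoires.

## Numerical and design choices

* Persistence-type coupling in the simulator redistributes each lineage's
  composition mass between naive and memory/effector subtypes by
  `persistent_fraction`; the planted per-sample composition is therefore
  recorded after this adjustment, and multinomial recovery guarantees hold
  exactly at the major-type level (within T/B subtypes, clone-level
  clustering inflates variance beyond multinomial).
* The power-law exponent fitter is an untruncated discrete (Hurwitz-zeta)
  MLE, adequate far from the truncation point; the sampler never uses it,
  so it serves as an independent check.
* Dirichlet draws with zero concentration entries keep those entries
  exactly zero instead of failing.
* Degenerate Welch inputs (both groups constant and equal) return t = 0,
  p = 1 by definition of "no difference".
* The pipeline manifest hashes the canonical JSON of the config and the
  bytes of every output file; end-to-end determinism is asserted by
  comparing manifests of two runs.
* Acceptance-style checks run at desk scale (cohorts of 10³–10⁴ cells,
  hundreds of fuzz/calibration replicates), sizes chosen so the binomial
  error of the measured rates is well below the asserted margins.

## Known limitations

* Persistence is presence/absence per time point; there is no abundance
  model or statistical test for clonal expansion beyond the descriptive
  fold rule.
* Single-chain ("partial") keys are never matched to paired keys; a cell
  whose second chain drops out therefore starts a new clonotype rather
  than joining its true one — conservative for persistence claims.
* The AIRR-C rearrangement schema is not read or written (a plausible
  extension); inputs follow the Cell Ranger CSV dialect.
* Epitope-specificity inference and hypermutation-based lineage analysis
  are out of scope.
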