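# Methods

This note documents the models, conventions and design choices behind
`hepnet`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what each stage assumes, which parameters matter,
and what the synthetic benchmark does and does not demonstrate.

## Synthetic multi-cohort generator

The generator emulates the design of a multi-cohort clinical coexpression
study: several independent cohorts profiled on a shared gene universe,
with functional gene modules whose coregulation is driven by hub genes.

Construction, per cohort and module: a latent factor *f* ~ N(0, 1) is
drawn per sample. Each **driver** gene equals *f* plus small noise
(sd 0.1·`noise_sd`), each **member** gene equals β·driver + ε. The member
noise sd is calibrated as ε_sd = `noise_sd`·sqrt(β²·Var(driver)·(1−ρ)/ρ),
so the expected member–member correlation equals ρ exactly at
`noise_sd` = 1 and tends to 1 as `noise_sd` → 0. `noise_sd` is therefore a
global noise *scale*, not an absolute sd. Background genes are independent
N(0, `noise_sd`); a per-gene baseline (~N(8, 1), shared across cohorts)
and a per-cohort additive per-gene batch shift (~N(0, `batch_shift_sd`))
are added on top. Values are log2-scale intensities by convention.

The driver is, by construction, the topological hub: its correlation to a
member is √ρ-scale while member–member correlations are ρ, so edge weights
concentrate on the driver and the key-driver stage has a well-defined
ground truth. This was chosen over direct covariance sampling precisely
because key-driver recovery needs a topological truth, not just a
correlation block.

Defaults (the package's reference study): 3 cohorts × 80 samples — the
scale of the smallest cohort in the clinical studies this design mirrors
(cohorts of roughly 80–230 patients) — three modules of 12/16/20 genes
with one driver each, ρ = 0.6, β = 0.9, `noise_sd` = 1,
`batch_shift_sd` = 0.3, 50 background genes, signature effect δ = 2 (log2
units). ρ and β are calibration choices for a clearly-but-not-trivially
detectable structure; no quantitative correlation structure is published
for the clinical cohorts.

Randomness: one PCG64 stream per cohort, seeded with
`SeedSequence([seed, cohort_index])` (baseline stream uses index 2¹⁶), so
adding a cohort never perturbs earlier cohorts and identical spec + seed
is bit-identical across platforms.

What the generator does **not** emulate: RNA-seq count noise and library
size, multiplicative/nonlinear batch effects, overlapping modules,
correlated background, missing-not-at-random values, and population
structure among samples. Passing the recovery benchmarks therefore shows
the pipeline recovers idealized planted structure at realistic sample
sizes — not that it would perform identically on clinical arrays.

## Edge meta-analysis

* Correlation metric: Pearson on log2 values (Spearman behind a switch).
  The test is two-sided on |r|: coexpression sign is not restricted.
* Permutation p-values use the add-one estimator (1 + b)/(B + 1), which
  can never be 0 and therefore never produces infinite ICS terms.
  Exhaustive enumeration (length ≤ 8) returns the exact permutation
  fraction.
* Per-pair sub-seeds are `seed XOR crc32(gene_a, gene_b)`, making the edge
  table independent of evaluation order and reproducible pair-by-pair.
* Missing values: pairwise complete-case with ≥ 3 shared observations;
  pairs below the floor are dropped and logged.
* The resampling null for ICS draws k p-values with replacement from the
  pool of **all** observed per-cohort nominal p-values (shared across
  edges, as a single null distribution). The bulk edge table draws this
  null once (10,000 draws by default) and reads each edge's add-one tail
  via binary search — identical to evaluating the per-edge operation
  against a shared null, at a fraction of the cost. With a Uniform(0,1)
  pool the null converges to chi-square with 2k degrees of freedom; this
  is asserted in the tests at KS D < 0.02.
* Because the pool contains the true edges' small p-values, the null is
  slightly heavy-tailed, making the meta p conservative for null edges —
  the FDR level is respected, at a minor power cost.
* Genome-scale all-pairs permutation testing is not desk-feasible; the
  default gene subset is the top 500 by pooled variance (caller-overridable).

## Planar network and modules

* The planar filter is the classical greedy PMFG: edges by weight
  descending, lexicographic tie-break on the canonical pair, insert iff
  planarity holds (networkx's linear-time planarity test), stop at
  3(|V|−2) accepted edges. Every accept/reject decision is logged.
* "Multiscale" module detection is greedy modularity optimization at a
  resolution sweep (default 0.5, 1.0, 2.0) on the planar graph;
  deterministic given the fixed node ordering. Communities below
  `min_size` (default 10) are discarded.
* The scale-free fit index is the R² of the least-squares line through
  (log₁₀ k, log₁₀ P(k)). Distinct degree values serve directly as bins
  when there are ≤ 12 of them — an exact power law then fits with R² = 1 —
  otherwise degrees are geometrically binned into ≤ 10 occupied bins. The
  index is reported as a module diagnostic, not enforced as a filter,
  since no threshold is published for this analysis.

## Key-driver analysis

* Downstream genes of a candidate are its n-layer BFS neighborhood
  (excluding the gene; n = 0 gives the empty set).
* The enrichment statistic maximized over n = 1..5 is −log₁₀ of the exact
  hypergeometric upper tail of the module/neighborhood overlap in the
  network-node universe; ties in p prefer the smaller n. Fold enrichment
  is reported alongside.
* All module members are candidates by default; a `candidates` argument
  allows hub-only restriction. The universe defaults to all network nodes
  (overridable). Within-module multiplicity is BH-adjusted.
* Isolated module genes receive a vacuous result (p = 1, fold 0) rather
  than an error.

## GSEA and signature status

* Ranking metric: difference of group means on log2 scale, descending,
  gene-id tie-break (signal-to-noise available as an alternative).
* The running sum increments by |score|^w (w = 1 by default) normalized
  over the in-set total at hits and decrements by 1/(N − N_hit) at misses;
  it starts at 0 and ends at 0, and the ES is the signed extreme. With
  w = 0 this is the classical KS statistic. If the in-set weight total is
  zero, equal hit weights are used so the normalization identity is
  preserved.
* Significance: sample-label permutation when both groups have ≥ 3
  samples, else gene-set permutation (logged). The empirical p is the
  add-one tail of |ES| within the matching-sign null subset — the standard
  GSEA convention; counting against the full null instead stacks null
  p-values below 0.5 and was rejected for exactly that miscalibration.
  NES divides ES by the mean |null ES| of matching sign. A fully
  degenerate comparison (all ranking scores zero, e.g. test = reference)
  short-circuits to ES = 0, p = 1.
* Status rule: **poor** iff (poor subset induced at q < 0.25) or (good
  subset suppressed at q < 0.25) and the converse does not hold; **good**
  for the converse; **intermediate** otherwise, including conflicting
  double-significant calls, which are logged rather than resolved by a
  guessed dominance rule. FDR 0.25 is the conventional exploratory GSEA
  threshold; the pipeline and CLI expose it.
* Housekeeping z-scoring subtracts the per-sample housekeeping mean (so
  common per-sample shifts cancel) and then z-scores each gene across
  samples; constant rows map to zeros with a warning.

## Candidate shortlist and utilities

Annotation flags (high liver expression, liver-disease association,
druggability) are tri-state — True / False / unknown — because absence of
evidence must not masquerade as negative evidence; a required flag fails
on unknown. Unannotated drivers are kept in a separate section rather than
silently dropped. How such flags are derived from external resources is
out of scope; they are caller-supplied inputs (the synthetic pipeline
flags planted drivers true). The caliper tumor-volume helper implements
0.5·L·W².

## Problem sizes and numerical choices

Single analyses default to 1,000 permutations per pair and 10,000
resampling draws. The repeated simulation studies (`hepnet.benchmarks`,
`scripts/acceptance.py`) run 300 permutations and 4,000 resampling draws
per replicate over 20 seeds (40 for the signature studies) — chosen as the
point where Monte-Carlo error is far below the effect sizes being
measured while a full study completes in minutes on one core. Tie
comparisons in all empirical tails use a 10⁻¹² tolerance so exact ties
count as exceedances. Output floats are serialized at 10 significant
digits, which is what makes rerun checksums byte-identical.

## Known limitations

* The planar-filter + modularity module detector is a documented stand-in
  for the published multiscale planar analysis, whose exact filtering
  order, scale decomposition and scale-free criterion are not described in
  the source this package draws on; results at a single resolution are
  used for driver ranking.
* Key-driver analysis is purely topological on an undirected graph; no
  causal or directed claims are made.
* The resampling-null conservatism noted above grows with the fraction of
  truly coexpressed pairs; at genome scale (sparse signal) it is
  negligible.
* No gene-identifier mapping, survival modeling, or count-based
  differential expression; matrices are assumed already log2-normalized.
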