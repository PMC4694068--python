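# Methods

## Comparative-Ct quantification (qpcr)

Relative expression is `2^(−ΔCt)` with `ΔCt = meanCt(gene) − meanCt(reference)`
per kinase; fold change divides by the empty-vector control's relative
expression, so the control row is exactly 1. Conventions:

- **Efficiency.** Amplification efficiency is fixed at 100% (base 2). No
  standard-curve correction is attempted; the base is not configurable in
  this version.
- **Replicates** are averaged arithmetically on the Ct scale before
  differencing — the standard comparative-Ct convention — never on the
  linear `2^(−Ct)` scale. Replicates are pooled across samples per
  (kinase, gene) after checking that every (sample, kinase) group carrying
  target measurements also carries the reference gene.
- **Detection floor.** No Ct cutoff is imposed; values ≥ 40 cycles are
  accepted with a warning, values outside (0, 45] are rejected.
- **One canonical scale.** Fold changes stay linear inside `qpcr`; log2 and
  the 0–1 induction scale are representations owned by `profiles`.
- An incomplete kinase × gene matrix is a hard error, never silent NaN; a
  missing reference or control measurement is an error naming the kinase or
  gene.

## Staged hit-calling (screen)

Three boolean calls and their intersection: anti-proliferative
(`rel_prolif ≤ prolif_threshold`), SASP inducer (fold change ≥ threshold in
at least `sasp_min_genes` of the SASP panel), p16 inducer (single-gene
call). All thresholds are inclusive — a documented, testable tie rule — and
live in `ScreenConfig` (defaults 0.5; 2.0 in ≥ 2 of 4; 1.5). The published
screen this design follows reports no numeric cutoffs, so the defaults are
chosen to reproduce its funnel shape (a broad anti-proliferative set
narrowing to a three-way intersection) on synthetic data; they are
configuration, not constants. Calls operate on point fold changes without a
replicate-level statistical test, mirroring a single-pass screen design.
The Venn summary stores the seven exclusive regions; each set's size equals
the sum of its four regions, and the regions sum to the union.

## Induction profiles (profiles)

- **Scaled induction**: per gene, `s = (FC − 1)/(FC_max − 1)` maps no
  induction to 0 and the maximal induction to 1 (100%). The scale is
  defined on [1, FC_max] only; fold changes below 1 clip to 0 (logged), and
  a gene whose maximum is ≤ 1 maps to all zeros.
- **Spearman correlations** are computed between genes across kinases:
  midranks (average ranks for ties) via `scipy.stats.rankdata`, then the
  Pearson correlation of the rank vectors. Two-sided p-values use
  `t = ρ√((n−2)/(1−ρ²))` on n − 2 df; sidedness is a package choice. For
  n ≤ 9 an exhaustive permutation p-value is available (`p_mode="exact"`).
  Rank correlations within 5e−15 of ±1 are snapped to exactly ±1 (and get
  p = 0). A constant column has no rank variance: its correlations are NaN
  with a warning, never a silent 0. No multiplicity adjustment is applied
  to the correlation matrix by default.
- **Clustering** uses the correlation distance `1 − ρ` (range [0, 2]) with
  average linkage — chosen for determinism and convention in expression
  profiling, since the analysis this emulates names neither. The first
  merge therefore joins the most-correlated gene pair. Constant columns
  must be dropped first (hard error). Trees export to Newick via
  scikit-bio.
- Correlation input defaults to the linear fold-change matrix; because ρ is
  rank-based, log2 input gives identical results, and only the clipping in
  the scaled01 representation could change them.
- In the end-to-end pipeline, correlations and clustering are computed over
  the kinases called anti-proliferative (the first-stage selection), the
  set a screen actually profiles; correlating over the full library would
  let the ~84% of null kinases — whose ranks are pure noise — dominate.

## Over-representation (enrichment)

For overlap k between an L-gene query and a K-gene term in an N-gene
background: fold enrichment `(k/L)/(K/N)` is evaluated as an exact rational
before the final float (k = 0 is defined as 0 with a warning); the Fisher
p-value is the hypergeometric upper tail `P(X ≥ k)` summed in log space
from log-gamma binomial coefficients, with no normal approximation at any
size; the EASE score is the same tail at k − 1, so single-gene overlaps are
never significant and EASE ≥ Fisher always. EASE is the ranking default
(the convention of the annotation tool this column layout mirrors), plain
Fisher a flag. Benjamini–Hochberg adjustment (statsmodels) runs over all
terms with k ≥ `min_overlap` (default 2). N is taken from the collection
("population total" semantics), not recomputed from the union of sets.
Gene-symbol matching is case-insensitive.

The reported `percent` column is `100·k/L`. Published tables of this layout
print a % against a different, unrecoverable denominator (~441), and their
p-values depend on the tool's internal list/background construction —
neither is reproduced here, only the contingency counts and fold
enrichments are.

Numerical note: log-gamma round-off is ~1e−16·|ln Γ(N)| per pmf term, so
tail sums are exact to ~1e−12 for N in the hundreds and ~5e−11 at
N ≈ 5600 — far below any decision threshold in this context.

## Synthetic screens (synthetic)

The generator emulates the latent structure the analysis assumes, with
defaults frozen as the study conditions:

- 200 kinases plus an empty-vector control; 33 planted hits.
- Each hit j carries one latent program strength
  `e_j ~ TruncNormal(4, 1.5, ≥0)` in log2 units; non-hits have `e = 0`.
- Gene g responds with `loading_g · e_j`: loadings 1.0 for the four SASP
  components and three intracellular NF-κB targets (they co-vary tightly,
  reaching > 100× at the top of the effect distribution), 0.15 for p16.
  p16 additionally receives a hit-only independent effect
  `TruncNormal(0.7, 0.15, ≥0)` log2 — the minimal structure giving p16 its
  observed behavior: induced in essentially all hits but weakly (pooled
  median fold change ≈ 2.4, extreme tail ≈ 5×), positively yet more weakly
  correlated with the SASP, and on its own main branch under clustering.
  A zero-mean independent term cannot produce that behavior: it would
  center hit p16 fold changes on the call threshold.
- Noise enters on the Ct scale, `N(0, 0.2)` cycles per replicate (2
  replicates), which is where qPCR variation actually arises; baseline Cts
  per transcript are fixed at values typical of fibroblast cDNA (ACTB 18,
  silent cytokines 28–31). The reference gene never responds to the
  program.
- Proliferation: hits `N(0.3, 0.08)`, nulls `N(1.0, 0.15)`, clipped at 0,
  control exactly 1.
- All randomness flows from one integer seed through spawned
  `numpy.random.SeedSequence` streams (hit selection, effects, p16 term,
  Ct noise, proliferation), so sub-streams are independent and every output
  is bit-reproducible.

What the generator does **not** emulate: amplification-efficiency
variation, plate/batch effects, inter-gene noise correlation, partial
infection, or any mechanistic NF-κB dynamics. Passing recovery tests
therefore demonstrates the pipeline's correctness under the assumed latent
structure, not robustness to those real-data artifacts.

Under the frozen defaults (measured over 20-seed batches): staged selection
recovers the planted hits with mean sensitivity ≈ 0.95 and specificity
≈ 1.0; estimated log2 fold changes regress on truth with slope within
1 ± 0.05; and the two-cluster cut of the gene dendrogram isolates p16 from
the SASP + NF-κB group in ≥ 95% of runs.

`generate_genesets` plants terms with exact (K, k) overlap geometry against
a synthetic gene universe, for validating the enrichment stack against
printed contingency counts; filler terms never intersect the query.

## Problem sizes

Tests run synthetic screens at 30–200 kinases, 20–100 seeds per property,
exact-arithmetic oracle sweeps at N ≤ 200 (1,000 draws) and n ≤ 30 (500
matrices) — sizes at which the exact oracles are fast and the estimates
stable. The acceptance script works at the published geometry
(L = 18, N = 5590).

## Known limitations

- Single-efficiency, single-reference normalization; no multi-reference
  geometric averaging.
- Hit-calling is threshold-based; no replicate-level inference or FDR on
  calls.
- The exact permutation p is limited to n ≤ 9 (full enumeration).
- Enrichment assumes the query maps entirely into the background; ID
  mapping between annotation spaces is out of scope (collections are
  user-supplied files).
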