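# Methods

This document records the generative model, the algorithms, and the reasoning
behind the default parameters. Everything here is implemented in
`src/rootlink/` and exercised by the tests.

## Coordinates and data model

All genomic intervals are 0-based half-open `[start, end)`. Two intervals
overlap iff they share at least one base; touching intervals (`end == start`)
do not overlap. A gene's TSS is `start` on the plus strand and `end - 1` (the
last covered base) on the minus strand. Fragments carry
`(chrom, start, end, barcode, count)`; a fragment's length is `end - start`.

`MultiomeMatrix` pairs a gene × cell RNA count matrix and a peak × cell ATAC
count matrix over one shared barcode list — the same-cell contract that the
rest of the package relies on.

## The generator

`generate_multiome(SimConfig)` simulates root-tip nuclei from two conditions
(control, osmotic stress) and returns matrices, fragment-level ATAC data,
gene models, a per-cell table and a `TruthSet` of planted facts.

**Cell types.** Fifteen RNA-defined types (initial, quiescent center,
epidermis/trichoblast/atrichoblast, cortex, endodermis ×2, stele lineages ×5,
root cap ×2) with fixed proportions; counts per type use largest-remainder
rounding, and composition is identical across conditions (composition shifts
are deliberately out of scope; the abundance test then acts as a negative
control).

**RNA.** Each gene has a lognormal base weight; each of the 15 types has six
marker genes boosted 4× in their own type. Expected counts are scaled
per cell so every cell's expected library equals `rna_depth` times a
per-cell lognormal depth factor (`depth_sd_log`), then sampled
negative-binomially (`Var = m + φ m²`, `φ = dispersion`).

**ATAC.** Chromatin follows the lineage *group* (six groups: the five
differentiated lineages plus "Pr", the primary program of initials and the
quiescent center). Marker-gene promoter peaks are open across the marker's
whole group; a fraction of distal peaks is mildly elevated in a random subset
of types; expected in-peak rates are scaled per cell to `atac_depth` and
Poisson-sampled. Counts are materialized as fragments (plus off-peak
background fragments) so the fragment file and the peak matrix agree exactly.

**Planted links.** For each planted cCRE–gene link, a latent per-cell
activity couples the cCRE's accessibility and the gene's expression with
weight `link_strength`; `both`-scope links are active in the two conditions,
`stress_only` links only in stress cells. The truth table records
`(ccre_peak, target_peak, gene_id, scope)` where the target peak is the
gene's promoter peak.

**Primed initials.** A fraction `primed_fraction` of initial cells per
condition swaps its ATAC program for a differentiated lineage's program while
keeping initial-type RNA; the truth table records which cells and which
lineage.

### Generator contracts (why three modeling choices look the way they do)

The generator must make unlinked peak–gene pairs *true negatives* for a
correlation-based linker, because such a linker cannot distinguish direct
linkage from shared type-regulation. Three choices enforce that:

1. **Per-cell library scaling.** Expected count vectors are rescaled per cell
   (not per dataset). Normalized expression is a composition; if type totals
   varied, every non-structured gene's share would inherit one common type
   profile and correlate with every type-structured peak.
2. **Balanced marker weights.** All marker base weights are equal, so every
   type's marker load — and hence the expected library composition seen by
   non-marker genes — is type-independent.
3. **Linkage horizon.** Distal peaks within 250 kb of any marker-gene TSS get
   no type-structured elevation. With 15 types, the correlation between two
   independent type-structured profiles has a standard deviation of ≈ 0.28 at
   the type level; roughly 7% of such pairs exceed r = 0.5 no matter how many
   cells are observed. Keeping type-structured background outside the
   linkage distance constraint removes this irreducible confound instead of
   hiding it behind sampling noise.

## Quality control

- **Peak merging** unions strictly overlapping intervals across batches
  (touching peaks stay separate); widths are kept when strictly between 20
  and 10,000 bp.
- **Nucleosome signal** = mononucleosomal (147–294 bp) over sub-nucleosomal
  (< 147 bp) fragment counts per cell; cells with no sub-nucleosomal
  fragments (including cells with no fragments) get +∞ and fail the `< 2`
  cutoff.
- **TSS enrichment** = mean per-base fragment coverage in `[tss−100, tss+100)`
  over all TSSs, divided by coverage in the flanks `[tss−2000, tss−1900)` and
  `[tss+1900, tss+2000)`; zero flank with nonzero center gives +∞, zero both
  gives 0.
- **Cell filtering** applies six strict inequalities: 1,000 < ATAC counts <
  100,000; 1,000 < RNA counts < 25,000; nucleosome signal < 2; TSS
  enrichment > 1. Missing metrics raise with the offending barcode.

## Gene activity

A fragment contributes its count to every gene whose window — gene body
extended 2 kb upstream (strand-aware, clipped at 0) — it overlaps by ≥ 1 bp.
Unknown barcodes are skipped with a warning. The implementation is
interval-indexed; tests compare it against a quadratic brute-force oracle.

## Embedding and metacells

TF-IDF (count / cell total × cells / detecting cells), scaled by 10⁴,
`log1p`, truncated SVD with a seeded start vector and deterministic sign
fixing. Component 1 is depth-correlated (the reported `depth_correlation`)
and excluded from neighbor metrics. Metacells are greedy k-NN neighborhoods
(k = 50) visited in canonical barcode order; a candidate is rejected if it
shares more than 80% of members with an accepted metacell. Aggregated counts
are exact member-column sums, so counting invariants survive aggregation.

## Co-accessibility

Metacell columns are depth-normalized to 10⁴; the genome is tiled into
500 kb windows with 250 kb stride; within a window the column-standardized
covariance feeds a graphical lasso whose element-wise penalty is
`α · (1 + distance / 50 kb)`, effectively infinite beyond the 250 kb distance
constraint. The score of a pair is its partial correlation
`−Θᵢⱼ / √(Θᵢᵢ Θⱼⱼ)`, averaged over the windows containing the pair; pairs
with score > 0.1 are kept. `α` is tuned by bisection so that ≈ 10% of
within-constraint pairs stay nonzero per window.

The solver is block coordinate descent over columns; a column whose penalties
are all zero is solved by a single linear solve, making `α = 0` reduce
*exactly* to inversion of the (ridge-jittered, if singular) sample
covariance — the module's oracle, verified to < 10⁻⁶ against direct
inversion on random windows of up to 10 peaks.

## Gene-linked cCREs

Promoter windows are `[tss − 2000, tss + 200)` strand-aware. For each
thresholded pair with exactly one promoter-annotated member (pairs with zero
or two are discarded and tallied), the promoter peak is the target, the other
peak the cCRE, and the linked gene is the target's nearest gene by TSS
distance (ties to the smaller gene id). The cCRE is retained iff Pearson
r > 0.5 and p < 0.05 (both strict; t-distribution on n − 2 df) between its
accessibility and the gene's expression across metacells. With a grouping,
the test runs within each group and any pass retains the link.

Stress-specific links are the keyed difference on `(ccre_peak, target_peak)`
between conditions. Hot-point cCREs are those whose distinct-linkage count
strictly exceeds Q3 + 1.5·IQR (linear-interpolation quartiles); fewer than
four cCREs yield an empty set. CNS overlap reports the fraction of cCREs
containing ≥ 1 conserved noncoding sequence, with a two-proportion z-test
between the gl and hgl sets.

## Priming classification

Reference profiles are mean normalized gene-activity vectors per lineage
group, built from *non-initial* cells only: the initials are the cells being
classified, and primed initials would otherwise leak their borrowed programs
into the Pr reference and erase the margin the classifier depends on. Each
initial cell is assigned to the group with maximal Spearman correlation; ties
break toward Pr, undefined correlations fall back to Pr. The primed fraction
per condition is the fraction of initials not assigned `INIT.Pr`.

## Differential tests

- **Expression:** per-gene two-sided Wilcoxon rank-sum on library-normalized
  (10⁴, `log1p`) values; exact p-values for small tie-free groups (verified
  against full enumeration at 4 vs 4), normal approximation with tie
  correction otherwise; constant genes get p = 1. log2FC uses a pseudocount
  of 1 on the normalized scale; a gene passes with |log2FC| ≥ 0.25 and BH-
  adjusted p < 0.05. On null data the raw p < 0.05 fraction calibrates to
  0.05 (tested on 2,000 genes, 100 vs 100 cells).
- **Accessibility:** per-peak likelihood-ratio test comparing logistic
  regressions of group membership on detection + latent covariate versus the
  latent covariate alone (χ², 1 df). The default latent is the per-cell total
  ATAC count, which absorbs depth effects that would otherwise look
  differential. log2FC is on detection fractions with a 0.01 pseudocount;
  the pass rule is |log2FC| ≥ 0.125 and adjusted p < 0.05.
- **BH adjustment** is the step-up procedure, verified against
  `statsmodels.multipletests`.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `n_cells_per_condition` | 2,000 | cells | enough metacell support for the r > 0.5 filter; < 1 min generation |
| `n_genes` / `n_peaks` | 300 / 1,000 | — | smallest geometry where promoters, distal peaks and 250 kb windows coexist on 2 × 10 Mb chromosomes |
| `n_planted_links` / `n_stress_only_links` | 30 / 20 | links | two scopes exercise shared vs condition-specific recovery |
| `link_strength` | 0.9 | — | latent coupling high enough that planted metacell correlations clear 0.5 |
| `primed_fraction` | 0.6 | — | majority-primed regime; classifier must not default to Pr |
| `rna_depth` / `atac_depth` | 2,500 / 2,000 | counts/cell | sparse single-nucleus regime |
| `dispersion` | 0.3 | φ | realistic NB overdispersion |
| coaccess window / constraint | 500 kb / 250 kb | bp | distal regulation range; penalty scale 50 kb |
| linkage predicate | r > 0.5, p < 0.05 | — | strict; r is the binding constraint at metacell counts |
| hot-point fence | Q3 + 1.5 IQR | links | standard upper-outlier rule |

## Numerical and scope notes

- Determinism: every stochastic step takes a seed (`SimConfig.seed`, SVD
  start vector, acceptance-script sub-seeds drawn below 2³¹).
- Metacell seeds are accepted under a pairwise-overlap rule; at the default
  k = 50 with ~2,000 cells most seeds are accepted, so metacells overlap and
  p-values on metacell units are anticonservative. The linkage decision is
  therefore dominated by the r > 0.5 bar, which the planted links clear and
  the background does not (by the generator contracts above).
- Correlation units are pooled per-condition metacells. Per-cell units were
  evaluated and rejected: Poisson noise attenuates planted per-cell
  correlations to the threshold's edge. A per-cell-type grouping was likewise
  rejected as the default: within-group effective sample sizes are too small
  for a stable p-value.
- The generator is a model organism for the algorithms, not a biological
  claim: composition is fixed across conditions, chromatin programs are
  group-constant, and planted links are the only peak–gene couplings within
  the distance constraint of type-structured genes.
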