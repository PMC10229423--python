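# Methods

This note documents the statistical procedures the package implements, the
choices that were genuinely open, and what the synthetic-data generators do
and do not emulate.

## Count normalization and fold changes

All screen comparisons operate on `v = log2(reads / column_total × 10⁶ + 1)`
— reads per million with a pseudocount inside the logarithm. The pseudocount
keeps zero counts at exactly 0 and bounds fold changes of low-count
elements; it also gives the exact per-sample identity
`Σ(2^v − 1) = 10⁶`, which the tests verify to relative 10⁻⁶. The same
formula is applied in every module (ORF screens included): one code path,
one documented transform. A log2 fold change is always a difference of
normalized values, so swapping sample and reference negates it exactly.

## Two-sample test and FDR

The screen test is the two-sided pooled-variance (Student's) *t*-test with
df = n₁ + n₂ − 2, computed from the closed form; `scipy.stats.ttest_ind`
serves as an independent reference in tests, never as the implementation.
Screens with n = 2 replicates per arm make zero pooled variance a real
possibility in noise-free synthetic data, so the degenerate case follows a
documented convention: p = 1 when the group means are equal, p = 0
otherwise, with a warning. Per-element p-values are reported without
multiplicity adjustment; where an FDR is defined (lineage enrichment,
biomarker ranking) it is Benjamini–Hochberg, delegated to statsmodels and
cross-checked in tests against a brute-force step-up implementation.

## CRISPR z-score essentiality

Order of operations: per-sgRNA LFC against the pre-swap reference (one
shared reference, or one per replicate matched by replicate number) →
per-gene mean over sgRNAs within a replicate → mean across replicates →
expression filter → z-transform. Genes whose log2 FPKM is below the
threshold (default 0, strict `<` removal) are excluded from scoring; genes
with no recorded expression at all are excluded everywhere.

Two empirical nulls are implemented because both are defensible and they
answer slightly different questions:

- **expression** (default): the *k* genes with the lowest recorded
  expression. These are genes whose knockout should be inert, so their
  LFC spread estimates technical noise. Sub-threshold genes remain
  eligible as null members even though they are not scored. Ties at the
  k-th expression rank break lexicographically by gene id. *k* defaults to
  20% of the genes with expression values on synthetic screens and should
  be set to 3,726 at full genome scale.
- **noncutting**: the non-cutting control pseudo-genes (controls are
  grouped into pseudo-genes of the same size as real genes so their
  gene-level noise is comparable).

The null sd is the sample standard deviation (ddof = 1). By construction,
z-scoring null members against their own null yields mean 0 and sd 1 to
machine precision; this self-consistency is an invariant under both modes.

Differential essentiality classes use explicit artifact conventions —
essential when z ≤ −3, dispensable when z > −1, condition-specific when
essential in one and dispensable in the other — configurable and clearly
not measured quantities. Ranking by `dz = z_u − z_glu` is the primary
output; the class column is a convenience.

## PRISM growth analysis

Equation order mirrors the assay description: low-count masking on raw
replicate counts (floor default 20 — "unexpectedly low" is not a measured
constant, so the floor is conservative and surfaced in configuration),
arithmetic mean collapse of the surviving replicates, then
`lfc = log2(n_u/n_g)` and `growth rate = log2(n_f/n_0)/t` (t default
6 days, seeding default 200 cells/line). Collapsed zeros or fully masked
conditions give missing metrics, never ±∞ or 0. Counts enter the
equations unnormalized; an optional per-sample RPM pre-scaling is not
applied by default because the equations are ratios within a line across
conditions and pool-composition effects cancel to first order only with
matched depths — users with unmatched depths should normalize upstream.

Lineage enrichment uses the simplest defensible test — members vs rest on
lfc with the pooled *t*-test — with BH FDR across the tested lineages;
lineages with fewer than 3 members are flagged untested rather than
silently included. Biomarker ranking is Pearson correlation
(pairwise-complete, features with < 3 complete lines or zero variance
excluded), with p from the *t*-distribution transform of *r* and BH within
feature class; Spearman is available behind a flag.

## Isotopologue correction

For an n-carbon metabolite the natural-abundance matrix is lower
triangular with `C[i,j] = Binomial(n−j, p).pmf(i−j)`, p default 0.0107
(IUPAC representative ¹³C abundance). Correction solves `C·x = raw/Σraw`
either exactly (`inverse`, a triangular solve; the solution sums to 1
automatically because columns of C are probability distributions) or by
nonnegative least squares (`nnls`, default for real data, where noise can
push the exact solution slightly negative), followed by renormalization.
Only carbon is corrected: for a ribose-ring ¹³C₅ tracer the dominant
interference is natural ¹³C, and N/H/O isotopes and tracer impurity are
out of scope. Summaries are `fraction labeled = 100 × (1 − M0)` and
`mean enrichment = Σ i·Mᵢ / n`.

## Synthetic data: what it emulates, and what it does not

Generators draw baseline element abundances lognormally (σ = 0.5) and
counts negative-binomially (gamma–Poisson, `Var = μ + αμ²`) around them;
planted effects multiply the expected final count by `2^effect` over the
screen window. Defaults reflect the emulated study designs: CRISPR screens
with 4 sgRNAs/gene, duplicate arms, 500 reads/sgRNA, dispersion 0.1, a
20% low-expression pool and 100 genes planted at −4 log2 in uridine; ORF
screens with 2,000 elements, duplicates, 20 ORFs planted at +3 log2 and
dispersion 0.01 at depth 1,000 (count CV ≈ 10%); PRISM with 482 lines in
22 lineages, triplicate wells, a +2 log2 planted lineage shift, and one
feature among 2,000 generated at population correlation 0.6 with the
latent growth lfc. The PRISM generator ties barcode counts to latent cell
numbers (seed 200 cells, per-line growth rate ≈ 0.5 doublings/day) so the
growth-rate equation recovers meaningful values.

Passing recovery tests on these data shows the *pipeline arithmetic and
ranking logic* are sound under the declared noise model. It does not show
robustness to what the generators deliberately omit: guide-efficiency
heterogeneity, lentiviral recombination artifacts, PCR jackpotting,
barcode collisions, batch structure in omics features, or correlated
features — real screens have all of these. Problem sizes in the test
suite and acceptance script (hundreds to 2,000 genes/features, 100
simulation seeds) are the package's chosen defaults for routine
verification; generators accept paper-scale sizes (76,441 sgRNAs, 17,255
ORFs) via `--paper-scale`.

All generators derive independent substreams from a single master seed
(`numpy` `SeedSequence.spawn`), and writers emit fixed 6-significant-digit
floats in deterministic column order, so any simulate + score pipeline is
byte-identical under a repeated seed.

## Numerical conventions

- Sorting everywhere uses stable merge sort with explicit id tie-breaks,
  so outputs are order-deterministic.
- `−log10(p)` in volcano tables caps at 300 when the degenerate p = 0
  convention fires.
- Zero-total count columns, all-zero MIDs, degenerate (zero-variance)
  nulls, sub-2 replicate arms and out-of-range p-values or abundances are
  rejected with named errors rather than propagated as NaN.
- Missing values propagate as missing (never coerced to 0), and inner
  joins between condition gene sets are logged.

## Known limitations

- The expression-mode null assumes low-expressed genes are phenotypically
  inert; in media where basal pathways matter this can inflate σ₀ and
  mute z-scores.
- The lineage test ignores within-lineage covariance (shared subtype
  structure) and treats lines as exchangeable.
- Pearson biomarker ranking is sensitive to outlying lines; use the
  Spearman flag for heavy-tailed features.
- MID correction assumes the instrument resolves only nominal mass shifts
  (no tracer isotopic impurity model, no positional information).
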