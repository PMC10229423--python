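# nutriscreen

Statistics for **nutrient-sensitized pooled genetic screens** — the kind of
experiment that asks which genes let cells survive when their preferred fuel
(glucose) is taken away and an alternative (galactose, uridine) is offered.
The package is aimed at functional-genomics analysts who have element×sample
barcode or sgRNA count tables in hand and want a small, tested, deterministic
pipeline rather than a platform.

It implements four analyses that share one statistical core:

1. **ORF gain-of-function screen scoring** — barcoded open-reading-frame
   overexpression constructs compete in two media; per element,
   `lfc = mean_b(v) − mean_a(v)` on the normalized scale with a two-sided
   pooled-variance (Student's) *t*-test across replicates.
2. **CRISPR knockout essentiality by normalized z-score.** Counts are
   normalized as `v = log2(reads / total_reads × 10⁶ + 1)`; each sgRNA's
   log2 fold change is taken relative to the pre-swap reference sample; the
   four sgRNAs of a gene are averaged within each replicate, then across
   replicates; genes with low expression (log2 FPKM < 0) are removed; and
   each gene is scored as `z = (LFC − μ₀)/σ₀` where (μ₀, σ₀) come from an
   empirical null — either the *k* lowest-expressed genes (*k* = 3,726 at
   genome scale) or the non-cutting control pseudo-genes. Differential
   essentiality between media is `dz = z_u − z_glu`.
3. **PRISM multiplexed growth metrics** for pooled barcoded cell-line
   collections: after masking suspiciously low replicate counts and
   mean-collapsing,
   `lfc = log2(n_u / n_g)` and `growth rate = log2(n_f / n_0) / t`
   (doublings/day), followed by lineage enrichment (members-vs-rest
   *t*-test with Benjamini–Hochberg FDR across lineages) and biomarker
   ranking (Pearson *r* between a molecular feature and growth, FDR within
   feature class).
4. **Natural-abundance correction of ¹³C isotopologue distributions**: the
   measured MID is `C·x` where `C[i,j] = Binom(n−j, p)` gives the chance of
   `i−j` naturally occurring heavy carbons (p ≈ 0.0107); correction inverts
   the convolution (triangular solve or NNLS) and reports the fraction of
   the pool carrying label, `100 × (1 − M0)`.

Every stage has a synthetic-data generator with planted ground truth
(negative-binomial counts, configurable dispersion, bitwise-reproducible
from a seed), so the whole pipeline is testable without any download.

## Worked example

Simulate a 500-gene knockout screen with 25 genes planted as
uridine-specific essentials (4 sgRNAs/gene, duplicate screens, 500
reads/sgRNA), then score it:

```sh
$ cat params.yaml
n_genes: 500
n_noncutting: 80
n_planted: 25
depth: 500.0

$ nutriscreen simulate crispr --params params.yaml --seed 42 --out sim
$ nutriscreen crispr-score --counts sim/counts.tsv --samples sim/samples.tsv \
    --library sim/library.tsv --expression sim/expression.tsv --out genes.tsv
INFO nutriscreen: scored 405 genes -> genes.tsv

$ head -4 genes.tsv | tail -1; grep -v '^#' genes.tsv | head -3
# param null_mode=expression
gene	mean_lfc_glucose	mean_lfc_uridine	z_glucose	z_uridine	dz	class
G180	0.0939263	-4.28649	0.536097	-18.655	-19.1911	uridine_specific_essential
G441	-0.252985	-4.40166	-0.962779	-19.1535	-18.1908	uridine_specific_essential
```

405 of the 500 genes pass the expression filter (the rest form part of the
low-expression null pool). Gene `G180` barely moves in glucose
(z ≈ 0.54, indistinguishable from the null) but its sgRNAs drop ~4 log2
units over the screen window in uridine (z ≈ −18.7), so it is classified
`uridine_specific_essential` — the planted behaviour. In this run all 25
planted genes occupy the 25 most-negative `dz` values, and the output
header records the fitted null (k = 100, σ ≈ 0.23 in both media) plus
SHA-256 checksums of every input.

The tracer module works the same way from Python:

```python
>>> from nutriscreen.tracer import natural_abundance_matrix, correct_mid, fraction_labeled
>>> C = natural_abundance_matrix(5, 0.0107)        # 5-carbon metabolite
>>> measured = C @ [0.35, 0.02, 0.03, 0.02, 0.03, 0.55] * 2.4e6
>>> corrected = correct_mid(measured, method="nnls")
>>> corrected.round(4)
array([0.35, 0.02, 0.03, 0.02, 0.03, 0.55])
>>> round(fraction_labeled(corrected), 2)
65.0
```

i.e. after removing natural-abundance contributions, 65% of the pool
carries tracer-derived ¹³C.

## Layout

| module | contents |
| --- | --- |
| `nutriscreen.core` | count containers, log2-RPM normalization, fold changes, t-test, BH FDR |
| `nutriscreen.io` | TSV dialects, sample sheets, provenance headers |
| `nutriscreen.orf` | ORF screen scoring and volcano tables |
| `nutriscreen.crispr` | gene-level LFC, empirical nulls, z-scores, differential essentiality |
| `nutriscreen.prism` | growth equations, low-count filter, lineage enrichment, biomarker ranking |
| `nutriscreen.tracer` | natural-abundance matrices, MID correction, labeling summaries |
| `nutriscreen.synth` | planted-truth generators for all of the above |
| `nutriscreen.cli` | `nutriscreen simulate / orf-score / crispr-score / prism-score / isocorrect` |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
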