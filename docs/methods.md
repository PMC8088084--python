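# Methods

`sexarch` analyses the genomic architecture of sex-biased gene expression
in a bulk RNA-seq design with two inbred lines, two sexes, three leg pairs
and three replicates (36 libraries), quantified against a genome dominated
by 13 large scaffolds, one of which is a hemizygous X.  This note records
the models, the parameter choices, and the limits of what the synthetic
tests demonstrate.

## Bias calling

A gene is *expressed* in a leg unless its FPKM is strictly below 2 in more
than half of that leg's 12 libraries, or its mean FPKM is strictly below 2
in both sexes.  Among expressed genes, a gene is *male-biased* in a leg
when its male/female fold change exceeds 1.5 (|log2FC| > log2 1.5 ≈ 0.585)
at an adjusted p below 0.05; *female-biased* symmetrically.  "Fold change
1.5" is interpreted on the linear scale.  Percentages in summary tables are
rounded half-away-from-zero to two decimals, so they reproduce printed
two-decimal tables exactly.

The differential-expression stage is a deliberately simple **stand-in**,
not a negative-binomial GLM: median-of-ratios size factors, group means of
normalized counts with a 0.5 pseudo-count for log2FC, a two-sided rank-sum
p (exact null when each group has ≤ 8 samples — the asymptotic
approximation is too coarse at n = 6 vs 6 to survive Benjamini–Hochberg
correction across thousands of genes), and BH adjustment within each
contrast.  Sex contrasts pool the two lines.  Every downstream analysis
consumes only (baseMean, log2FC, padj), so externally computed tables
(e.g. from DESeq2) can be supplied instead and are the recommended input
for real data.  There is no dispersion shrinkage: at n = 6 vs 6 the
stand-in's p-value floor is 2/924 ≈ 0.0022, which bounds attainable
sensitivity when the number of truly biased genes is small.

## Fold-change reassignment

For the genome scans every gene carries one *adjusted* log2FC per leg:
unexpressed genes get (0, p = 1), unbiased expressed genes get log2FC 0,
biased genes keep their estimate.  This makes window means directly
interpretable as local sex-bias mass and is idempotent.

## Sliding-window region scan

Scaffolds are split into 100 kb bins; windows of 20 bins (2 Mb) step one
bin.  A gene belongs to the bin containing its midpoint, so each gene
counts once per window.  The null shuffles adjusted log2FC values across
gene positions *within five expression strata* (baseMean quantile bins,
boundary values to the lower stratum): expression level correlates with
fold-change magnitude and with the chance of reaching significance, so an
unstratified shuffle would miscalibrate the null.  Empirical p-values use
the add-one rule, p = (1 + #{null ≥ obs})/(n_perm + 1).

A window is called enriched when its empirical p is at or below the
effective per-window alpha

    alpha_eff = max(1 − quantile_cutoff, 1 / (n_perm + 1)),

with quantile_cutoff = 0.9999 by default (the 99.99% quantile, i.e.
alpha = 1e-4 at the reference 100,000 permutations).  The floor term is
the attainable minimum of the add-one p-value; at reduced permutation
counts it keeps the caller operational and is always reported alongside
the configured alpha.  Optionally the alpha is further divided by the
number of independent (non-overlapping) windows — total scaffold length /
window span — for a Bonferroni-style correction; this is off by default
and exposed as `divide_by_independent`.  Windows with fewer than 5 genes
are never called.  Contiguous same-direction calls merge into regions.

Null storage is bounded: per-window exceedance counts against the observed
means plus the top/bottom 0.5% tails, so quantile queries in the calling
range stay exact without holding an n_perm × n_windows matrix.

## Consecutive-gene clusters

Genes are ordered along each of the 13 largest scaffolds; a cluster is a
maximal run of ≥ 2 consecutive same-direction biased genes (any unbiased
gene or opposite direction breaks the run; runs never span scaffolds).
The null redistributes the observed label multiset uniformly over all gene
positions (scaffold structure preserved), 1000 iterations by default, and
reports the mean and central 95% fluctuation interval of (a) the clustered
proportion per direction and (b) the count of clusters in each size class.
An observed value outside its interval is flagged with its side.  At label
density p the null clustered proportion is ≈ 1 − (1 − p)², which the tests
use as an independent closed-form check.  The default label universe is
all annotated genes on the 13 scaffolds; an expressed-only universe is a
config option, because the choice materially changes the null density.

A practical note from the calibration experiments: a handful of planted
small clusters moves the per-size-class counts far outside their bands
long before it moves the overall clustered proportion, which is dominated
by background density; the per-size statistics are therefore the sensitive
readout for small planted structure.

## X chromosome, Y scan, dosage compensation, enrichment

Male-only genomic coverage identifies the X: among the 13 largest
scaffolds, the unique one whose depth ratio to the median of the others
falls in [0.35, 0.65] (about half, with room for Poisson noise at
desk-scale depths).  Zero or multiple candidates leave the X unassigned
with diagnostics.  A Y candidate would combine X-like coverage with
exclusively male-biased expressed genes; the scan covers the 50 largest
scaffolds.  Dosage compensation is tested per leg by a two-sided rank-sum
comparing per-gene male vs female mean log2(FPKM) on the X (genes with
FPKM > 2 in at least half the leg's libraries; replicates and lines
averaged first, the gene is the unit of observation).  Chromosomal
enrichment uses Fisher's exact test (two-sided, point-probability
convention; sample odds ratio reported) on {biased, not} × {X, autosome}
over the leg's expressed genes, with the autosome set fixed to the 12
largest non-X scaffolds.  The sex×leg crosstalk test crosses one leg's
sex-bias calls with the within-sex leg-contrast calls on the same
expressed universe and reports the overlap count, percentage and Fisher p.

## dN/dS comparisons and the label bootstrap

Per-gene per-branch dN/dS ratios (dS = 0 excluded and counted) are
compared between bias categories by two-sided rank-sum tests.  Because an
observed p-value for a small category against a large unbiased pool can be
fragile, a label bootstrap re-draws the category labels at random without
replacement (253 male / 463 female by default, matching the observed
category sizes), recomputes the tests 1000 times, and takes the p-value
that 99.95% of random relabelings exceed as the cutoff; the observed
contrast is declared non-random only below it.  Upstream steps (orthology,
alignment, tree, rate estimation) are consumed as a table and are out of
scope.

## Synthetic data

The generator emulates the study conditions and is itself first-class,
tested code.  Defaults:

| parameter | default | basis |
|---|---|---|
| scaffolds | 12 autosomes + X, 5 Mb each | 13 large scaffolds; desk-scale length |
| gene spacing | exponential gaps, mean 20 kb, min 1 kb | ~1 gene / 20 kb |
| design | 2 lines × 2 sexes × 3 legs × 3 reps | the 36-library design |
| baseline expression | lognormal(log 100, 1.2) per gene | conventional bulk RNA-seq spread |
| NB dispersion | 0.1 | conventional bulk value; not fitted to the study |
| library sizes | lognormal, sd 0.2 | forces normalization to matter |
| bias fractions per leg | 1.80/4.45, 1.91/3.97, 6.02/11.47 % (M/F) | the observed per-leg rates |
| planted effect | log2FC 2 | comfortably above the 1.5-fold threshold |
| planted region | 2 Mb on scaffold_2, 30 male genes | the megabase-scale cluster condition |
| planted clusters | sizes 3, 2, 4 on scaffolds 4–6 | small-run condition |
| X feminization | ×3 female-bias density, leg 3 only | the feminized-X condition |
| dosage compensation | full (equal expectation per sex on X) | makes the dosage test a calibrated null |
| coverage | Poisson window depths, D = 100 (X: D/2) | half-coverage X identification |
| dN/dS | gamma(2, 0.075); male category scale ×1.3; 253/463/rest | category-shift condition |

Exponential gaps (memoryless) rather than a fixed grid give realistic
variance in per-window gene counts.  One global seed is split
hierarchically per generator stage, so each stage is independently
reproducible.  The truth record stores every planted label, region,
cluster, the X identity and the dN/dS categories.

What the generator does **not** emulate: isoform structure, GC/length
biases, correlated expression between neighbouring genes (beyond planted
structure), batch effects beyond a single line shift, partial dosage
compensation, and any sequence-level signal.  Passing recovery tests
therefore demonstrates that the machinery is correct and calibrated under
the stated statistical structure, not that the stand-in DE stage matches a
negative-binomial GLM on real libraries.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; GFF3 converts at
  the boundary (1-based inclusive on disk).
- Quantile strata break ties downward; degenerate strata (few distinct
  baseMeans) are allowed and logged.
- Windows truncated by a scaffold end are dropped; scaffolds shorter than
  one window yield no windows.
- All-zero count groups give log2FC 0, p 1; a zero library column gives a
  zero abundance column with a warning.
- Empty Fisher margins give p = 1 with an undefined-odds-ratio flag; a zero
  denominator in cluster proportions gives an explicit undefined flag.
- Cluster size classes are tracked exactly up to size 12 (larger runs are
  aggregated); runs of that length do not occur at realistic densities.
- Every permutation machinery takes an explicit seed and is byte-identical
  across reruns at a fixed seed.

## Problem sizes used in the shipped tests

Recovery and calibration suites run at reduced Monte-Carlo depth chosen as
the package's own test scale: 2,000 permutations for the region scan
(reference default 100,000), 1000 iterations for cluster and dN/dS
resampling, 20–200 seeded repetitions per calibration claim.  The
acceptance script reruns the full synthetic pipeline at the same scale.
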