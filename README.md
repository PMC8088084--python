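# sexarch

Genome architecture of sex-biased gene expression: a tested pipeline for
calling sex-biased genes from replicated bulk RNA-seq contrasts and asking
*where they sit in the genome* — on the X or the autosomes, in
megabase-scale enriched regions, or in runs of consecutive same-direction
genes — plus a resampling guard for dN/dS comparisons between bias
categories.

The package targets the common design in studies of sexually dimorphic
traits (here, water-strider legs with exaggerated male third legs): two
inbred lines × two sexes × three tissues × three replicates, a genome
dominated by 13 large scaffolds, and a hemizygous X recognizable by its
half coverage in male-only genomic sequencing.

## What it computes

- **Bias calls** per tissue: a gene is male-/female-biased at fold change
  > 1.5 and adjusted p < 0.05, on top of a 2-FPKM expression filter; calls
  collapse into an adjusted log2FC vector (unexpressed/unbiased → 0).
- **Chromosome-level tests**: X identification from coverage ratios, a Y
  candidate scan, per-leg dosage-compensation rank-sum tests, Fisher exact
  X-vs-autosome enrichment, and the sex×leg crosstalk enrichment.
- **Region scan**: mean adjusted log2FC in 2 Mb windows stepping 100 kb,
  against a permutation null that shuffles values within five expression
  strata (lowly expressed genes have wilder fold changes, so stratifying
  keeps the null honest); windows beyond the 99.99% empirical quantile are
  called and merged into regions.
- **Consecutive-gene clusters**: maximal runs of ≥ 2 same-direction biased
  genes per scaffold, tested against 95% fluctuation intervals from 1000
  label permutations, per direction and per cluster size.
- **dN/dS comparisons** between bias categories with a label bootstrap:
  category labels are re-drawn at random (253 male / 463 female by
  default) 1000 times and the observed rank-sum p is declared non-random
  only if it beats the cutoff that 99.95% of random relabelings exceed.
- **Synthetic data**: a generator that emulates the full design with
  planted, scoreable effects (bias fractions per leg, a 2 Mb enriched
  region, small gene runs, a feminized half-coverage X, dN/dS category
  shifts) and a ground-truth record for recovery testing.

## Worked example

Run the full pipeline on synthetic data (desk-scale permutation counts):

```bash
sexarch all --seed 1 --outdir run1 --n-perm 2000 --n-iter 1000
cat run1/report.txt
```

which prints (abridged):

```
Sex-biased genes per leg:
  leg 1: 3244 expressed; 98 male-biased (3.02%), 138 female-biased (4.25%)
  leg 2: 3246 expressed; 98 male-biased (3.02%), 121 female-biased (3.73%)
  leg 3: 3240 expressed; 243 male-biased (7.5%), 377 female-biased (11.64%)

X chromosome: scaffold_13 (coverage ratio 0.50)
  no Y candidates found

Enriched regions (5):
  scaffold_2:0-4100000 male (leg 1, 22 windows)
  scaffold_2:0-4100000 male (leg 2, 22 windows)
  scaffold_13:0-2000000 female (leg 3, 1 windows)
  scaffold_13:2200000-4400000 female (leg 3, 3 windows)
  scaffold_2:200000-4100000 male (leg 3, 20 windows)

Consecutive-gene clusters:
  leg 3 male: clustered proportion 0.235 vs null [0.082, 0.206] -> SIGNIFICANT

dN/dS comparisons:
  male_vs_unbiased: p=0.000166; bootstrap cutoff 0.004553 -> non-random
```

Reading this: the generator planted ~6%/11.5% male/female bias in leg 3
and the caller recovers those rates; the half-coverage scaffold is
identified as the X (ratio 0.50) and, because female-bias density was
tripled on the X in leg 3, the X surfaces as a female-enriched region;
the planted 2 Mb male region on scaffold_2 is called; planted gene runs
push the male clustered proportion above its null band; and the planted
×1.3 dN/dS shift in the male category is significant *and* survives the
label bootstrap.

The same pipeline runs on real inputs (`synthetic: false` in a YAML
config) from a gene annotation (GFF3/BED), a counts matrix with a sample
sheet, optional externally computed DE tables (e.g. DESeq2), a per-scaffold
male coverage table, and a per-gene dN/dS table.

## Library use

```python
from sexarch import SimulationConfig, PipelineConfig, run_pipeline
from sexarch import regions, clusters, chromosome

cfg = PipelineConfig(outdir="run1", seed=1)
manifest = run_pipeline(cfg)
```

Each analysis is also callable on its own (`regions.permute_profiles`,
`clusters.cluster_null`, `chromosome.fisher_x_enrichment`, ...) on plain
pandas objects; see `docs/methods.md` for the statistical details and the
synthetic generator's default conditions.

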