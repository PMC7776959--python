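# hzkit

Hybrid-zone analysis toolkit: from biallelic SNP genotypes and transect
coordinates to ancestry proportions, hybrid-class assignments, geographic
cline widths, morphological hybrid indices, and reciprocal-transplant
selection coefficients — plus a synthetic-data generator so every stage
can be exercised and tested without field data.

## What it does

| stage | module | method |
|---|---|---|
| Genotype / metadata I/O | `hzkit.io_core` | VCF (biallelic SNPs) or 0/1/2 TSV; shrunk parental allele frequencies |
| Ancestry (q) | `hzkit.ancestry` | supervised two-pool binomial ML, bounded 1-D optimization, Fisher SE |
| Hybrid classes | `hzkit.hybrid_classes` | six-category (P1/P2/F1/F2/BC1/BC2) genotype-frequency ML with log-space posteriors |
| Geographic cline | `hzkit.cline` | 10-m band means, four-parameter tanh cline by ML with multistart, within-band bootstrap CI for width |
| Leaf morphometrics | `hzkit.morphology` | scaled/centered PCA, per-individual axis-1 averages anchored at parental centroids (±2), progeny hybrid rate with Wilson CI |
| Transplant selection | `hzkit.selection` | composite fitness = survival × ln(1+biomass), per-habitat relative fitness, s = 1 − w, truncated percentile bootstrap; NB GLM (log link, profiled dispersion) + LR tests |
| Mortality tables | `hzkit.mortality` | hierarchical log-linear models via IPF, G² deviance, backward-stepwise search |
| Synthetic data | `hzkit.synthetic_data` | parental pools, admixed classes, tanh ancestry clines, ancestry-linked morphology, habitat×phenotype transplant outcomes |
| Orchestration | `hzkit.pipeline`, `hzkit.cli` | `run-zone` and `run-transplant` chains with JSON reports |

## CLI

Every stage is a subcommand of `hzkit`:

```bash
# synthetic fixtures with a truth JSON
hzkit simulate --seed 1 --n-loci 500 --n-query 150 --out-dir fixtures/

# individual stages
hzkit ancestry  --genotypes fixtures/genotypes.tsv --samples fixtures/samples.tsv --out q.tsv
hzkit classify  --genotypes fixtures/genotypes.tsv --samples fixtures/samples.tsv --out classes.tsv
hzkit cline     --genotypes fixtures/genotypes.tsv --samples fixtures/samples.tsv \
                --n-boot 500 --seed 2 --out cline.json --bands-out bands.tsv
hzkit morpho-index --morphology fixtures/morphology.tsv --samples fixtures/samples.tsv --out index.tsv
hzkit selection --transplant fixtures/transplant.tsv --seed 3 --out fitness.tsv
hzkit mortality --transplant fixtures/transplant.tsv --cause burial --out burial.json

# full chains
hzkit run-zone --genotypes fixtures/genotypes.tsv --samples fixtures/samples.tsv \
               --morphology fixtures/morphology.tsv --out-dir zone/ --seed 4
hzkit run-transplant --transplant fixtures/transplant.tsv --out-dir tp/ --seed 5
```

Logs go to stderr. Exit codes: 0 success, 1 domain/data error, 2 usage
error. Every stochastic stage requires an explicit `--seed`; reruns with
the same seed are byte-identical.

## File formats

All tables are UTF-8, tab-separated, with a header row.

* **Genotypes (TSV)** — first column `sample_id`, one column per locus,
  values `0`/`1`/`2` (ALT-allele dosage) or `NA`. VCF input keeps
  biallelic SNP records only (others are skipped and counted);
  half-missing genotypes are treated as missing.
* **Samples** — `sample_id`, `position` (signed meters from the ecotone
  midline, desert negative / dune positive), `habitat`
  (`desert|ecotone|dune`), `role`
  (`reference_P1|reference_P2|query`).
* **Morphology** — `sample_id`, `leaf_id`, then one numeric column per
  measurement (area + shape descriptors), one row per leaf.
* **Transplant** — `plant_id`, `phenotype` (`P1|P2|HYB`), `habitat`,
  `water` (`ambient|supplemented`), `survived` (0/1), `biomass`
  (grams, recorded at harvest or at time of death), `death_cause`
  (`alive|burial|herbivory|other`; `alive` iff `survived=1`).

## Conventions and caveats

* q is the admixture proportion toward pool P1; swapping pools maps
  q → 1 − q exactly.
* Cline width is the inverse of the maximum slope of the tanh cline.
* The morphological hybrid index anchors the reference-P1 centroid at
  −2 and reference-P2 at +2; because q runs toward P1, the
  genotype–morphology correlation is negative under the default
  conventions (its magnitude is what matters).
* The NB GLM accepts continuous ln(1+x) responses via the IRLS
  quasi-likelihood contract, mirroring the source analysis; a Gamma GLM
  is available as a cleaner alternative (`family="gamma"`).
* Only first/second-generation hybrid categories are modeled; deeper
  backcrosses fold into the nearest category.
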