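# arabpop

Population-genomics analysis toolkit built around a fully synthetic,
ground-truth-carrying cohort simulator. It covers the analytical core of a
large cohort study pipeline:

- **synthdata** — Balding–Nichols admixture simulation (K drifted ancestral
  populations, Dirichlet admixture proportions), planted autozygous tracts,
  a haploid locus evolving on a simulated ultrametric tree with
  cluster-private fixed mutations, and reference/target panel splits for
  imputation benchmarking. Every artifact ships with a truth registry.
- **qc** — per-sample missingness/outlier screening, exact conditional
  Hardy–Weinberg test, variant filters (missingness → minor allele count →
  HWE → exclusion regions), and multi-cohort site intersection.
- **structure** — LD pruning, genotype PCA, allele-sharing summaries, and
  dominant-ancestry assignment from admixture Q matrices.
- **fstats** — f3 admixture statistic, Patterson's D, Hudson and
  Weir–Cockerham FST, weighted block-jackknife errors, and admixture-network
  construction from significant f3 triples.
- **roh** — two-state HMM caller for runs of homozygosity, three-component
  Gaussian-mixture size classes on log10(length), excess-homozygosity
  inbreeding F, and gene-containment summaries.
- **ylineage** — support-collapsed tree clustering under patristic-distance
  cutoffs, cutoff-grid scans, fixed-SNP sub-haplogroup definition
  (haploid FST = 1, within-cluster derived AF = 1), mutation-count lineage
  dating with bootstrap CIs, and rank-sum group comparison.
- **imputeval** — variant-discovery saturation curves, pseudo-array masking,
  stand-in imputers (frequency dosage / nearest-haplotype copying), and
  pooled aggregate-R² accuracy binned by allele frequency.

File formats: uncompressed VCFv4.2 (diploid and haploid GT), BED, newick
with support labels, and TSV tables throughout.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: exact in-text
arithmetic checks plus calibration properties (D-statistic null over 40
seeds, f3 admixture detection, FST recovery at drift 0.148, jackknife
delete-one oracle at 1e-12, planted-ROH recall/precision ≥ 0.9,
Y-lineage end-to-end recovery, imputation-evaluator oracles, exhaustive
HWE enumeration for all tables with n ≤ 50).

## CLI

Run the full synthetic demonstration pipeline (simulate → qc → structure →
fstats → roh → ylineage → imputeval):

```sh
arabpop all --seed 1 --out demo_out
```

Individual stages (`arabpop simulate|qc|structure|fstats|roh|ylineage|imputeval`)
run with their required upstream stages. Configuration is a flat YAML file
with one section per module; unknown keys are rejected before any compute,
and the merged configuration is echoed into the output directory alongside
a structured JSONL run log:

```yaml
seed: 1
simulate:
  k: 3
  n_sites: 24000
qc:
  mac_min: 3
  hwe_p: 1.0e-5
```

```sh
arabpop all --config config.yaml --out demo_out
```

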