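# mtburden

Somatic mitochondrial-DNA mutational-burden analysis for paired tumor–normal
cohorts: somatic SNV calling from matched allele frequencies, rCRS region and
effect annotation, purity-adjusted burden metrics, and clinical association
analyses (ANOVA linear models, Kaplan–Meier/log-rank, ROC with a DeLong
paired-AUC comparison). A synthetic-cohort simulator with known truth makes
every stage testable fully offline.

## What it does

- **`mtburden.reference`** — packaged rCRS reference (NC_012920, 16,569 bp)
  with a region map of all 37 genes plus the control region (stored as two
  segments, 16024–16569 and 1–576, to express the circular wrap), the
  vertebrate mitochondrial genetic code, position lookup (`locate`), and
  strand-aware codon-level effect classification (`classify_effect`).
- **`mtburden.simulate`** — synthetic paired cohorts: Poisson per-patient
  burden with Gleason-category-dependent means, truncated-Beta heteroplasmic
  allele frequencies drawn in tumor-cell-fraction space and scaled by tumor
  purity, exponential relapse with a proportional-hazards multiplier for
  variant carriers, and binomial read-count emission.
- **`mtburden.calling`** — the somatic rule (tumor AF − normal AF strictly
  greater than 0.10; tumor gains only, losses routed to a diagnostics
  stream), pyrimidine-strand substitution spectrum, cross-patient
  deduplication, and catalog-based novelty annotation.
- **`mtburden.burden`** — purity-adjusted allele frequencies (uncapped),
  per-patient cumulative variant frequency (CVF), functional flags
  (adjusted AF > 0.70), cohort summary tables, per-region variant densities
  and exact enrichment tests.
- **`mtburden.stats`** — self-contained statistical engine: exact Fisher 2×2
  (integer enumeration) and Monte-Carlo r×c, OLS/ANOVA, Bonferroni,
  product-limit survival curves, log-rank with Mantel–Haenszel hazard
  ratios, empirical ROC/AUC, IRLS logistic predictor combination, the DeLong
  test, and PSA-series relapse classification.
- **`mtburden.pipeline` / `mtburden.cli`** — end-to-end orchestration with a
  YAML/JSON config, structured logging, TSV/VCF/JSON I/O and a cohort report.

## CLI

```bash
# simulate a 115-patient paired cohort (TSV + truth JSON, optionally VCFs)
mtburden simulate --n-patients 115 --seed 7 --out cohort/ --vcf

# validate inputs (exit code 2 on issues)
mtburden validate --variants cohort/calls.tsv --clinical cohort/clinical.tsv

# somatic calling only
mtburden call --variants cohort/calls.tsv --out called/

# full pipeline from a config file
cat > config.yaml <<EOF
seed: 7
output_dir: out
simulation:
  n_patients: 115
EOF
mtburden report --config config.yaml

# inspect the packaged reference
mtburden export-reference --out ref/
```

A file-based run replaces the `simulation` block with `variants_path` and
`clinical_path` (TSV; a catalog TSV for novelty annotation is optional). The
report is written as `report.json` and `report.txt` next to every
intermediate table (somatic calls, unique variants, burden profiles, region
densities, KM and ROC coordinate tables).

## Notes

- Coordinates are 1-based rCRS positions throughout; a variant in overlapping
  genes (e.g. ATP8/ATP6) keeps every region membership but resolves to the
  most severe single effect.
- Indels are parsed from VCF input but excluded from all burden statistics;
  the analysis is SNV-only.
- All randomness flows from a single seed through named per-stage substreams;
  reports are byte-identical across runs with the same config.
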