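# carefrag

Care-fragmentation analysis of EHR-style data, end to end on synthetic
inputs:

* **Phenotyping** — rule-based identification of five chronic-disease
  subgroups from diagnosis codes, labs and medications: asthma, chronic
  kidney disease (MDRD eGFR < 60 or dipstick proteinuria, two measurements
  ≥ 3 months apart), COPD (four alternative criteria at age ≥ 40), and
  diabetes (inpatient code or two qualifying events within two years) split
  into type 1 vs type 2 by code-count majority, glucagon/oral-agent
  prescriptions, C-peptide and autoantibody results.
* **Cohort constraint** — selects patients holding an in-system primary
  care physician who live within *d* km (Vincenty geodesic distance on
  WGS-84, boundary inclusive) of at least one in-system hospital.
* **Fragmentation metrics** — the percentage of a patient set's hospital
  visits (emergency + inpatient, from an all-payer registry table) that
  occur in-system, over 6- and 12-month follow-up windows, per subgroup and
  per hospital, plus a sweep of the curves over a *d* grid.
* **Synthetic generator** — produces datasets with configurable disease
  prevalences, PCP share, home-distance mixture, and an in-system visit
  model `p = logistic(b0 + b_pcp·PCP + b_dist·distance)`, plus a
  deterministic fixture suite covering every phenotype rule branch with a
  minimal positive and a near-miss negative.

## CLI

```bash
carefrag generate --out data --n 2000 --seed 7      # synthetic dataset (9 CSVs)
carefrag label --data data --out labels.csv          # phenotype flags + evidence
carefrag select --data data --d 8                    # constraint subcohort, n0/m0
carefrag report --data data --out outputs            # full report bundle
carefrag sweep --data data --out sweep_curves.csv    # curves over the d grid
carefrag verify-arithmetic                           # published-ratio parity check
carefrag run-all --out outputs --n 2000 --seed 7     # generate + everything
```

`run-all` emits `labels.csv`, `evidence.jsonl`, `subcohort.csv`,
`report_table2.csv` (per-subgroup fulfilling fraction and in-system
percentages for both windows), `per_hospital.csv`, `sweep_curves.csv`,
optional SVG figure analogs (`--plots`), and a `manifest.json` with config
hash and file checksums — identical inputs reproduce identical bundles.
Study parameters (cohort year, index date, windows, *d*, *d* grid,
phenotype-mode toggles, generator settings) live in a YAML config passed
via `--config`; flags override it.

## Data model

Nine CSV tables (UTF-8, ISO dates, header row): `patients`, `visits`,
`diagnoses` (explicit `code_system` icd9/icd10 and `rank`), `labs`,
`medications` (controlled `drug_class` vocabulary), `pcp`, `pregnancies`,
`facilities`, and `registry` (the all-payer hospital-visit feed). Loading
validates schemas, row invariants and cross-table referential integrity
with row/column-level error messages; write→load is a field-exact round
trip. The diagnosis-code vocabulary (wildcard patterns like `J45.x`,
`250.x2`, `J44.*`) ships as an editable data file
(`src/carefrag/data/code_sets.yaml`).

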