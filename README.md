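# faersig

Disproportionality signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) collect individual case safety reports (ICSRs): one patient, the
drugs they took (with reporter-assigned role codes), and the adverse
reactions coded as MedDRA preferred terms (PTs). Pharmacovigilance teams
mine these streams for drug–event pairs that are reported *disproportionately*
often, then ask how the risk evolves with time on drug. `faersig` packages
that workflow end to end for analysts who want a reproducible, testable
pipeline rather than a one-off script:

* **Ingestion & deduplication** — reads the `'$'`-delimited quarterly tables
  (DEMO/DRUG/REAC/THER/OUTC), joins them on `primaryid`, converts age/weight
  units, then removes duplicates in two stages: keep the latest version of
  each case (greatest `primaryid` per `caseid`), then collapse reports
  identical on the six-field redundancy key (event date, age, sex, reaction
  set, drug set, country) to the most recent receipt.
* **PT/SMQ mapping** — a bundled ten-PT osteoporosis group (or any custom
  PT list) is counted at the PT level and aggregated to the group level.
* **Four disproportionality statistics** per 2×2 table
  (a = target drug & event, b, c, d the complements, E = (a+b)(a+c)/N):

  | method | point estimate | signal criterion |
  |---|---|---|
  | ROR  | ad / bc, Wald CI on the log scale | CI low > 1 and a ≥ 3 |
  | PRR  | (a/(a+b)) / (c/(c+d)), with Pearson χ² | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
  | IC   | log₂((a+0.5)/(E+0.5)), Norén credible bounds | IC025 > 0 |
  | EBGM | DuMouchel gamma–Poisson shrinker posterior geometric mean | EB05 > 2 |

  plus a χ²/Fisher p-value per pair, Bonferroni correction across the run,
  and an at-least-one-method consensus flag.
* **Subgroup analysis** — sex strata and an age split at 60 years, each
  analysed with a stratum-internal background.
* **Weibull time-to-onset** — days from the earliest primary-suspect therapy
  start to the event date, fitted by maximum likelihood; the shape CI
  classifies the hazard as early / random / wear-out failure.
* **Synthetic data** — a generator that emits the exact FAERS dialect the
  reader consumes, with planted reporting-rate ratios, Weibull onset times,
  demographic mixes and injected duplicates recorded in a manifest, so the
  whole pipeline is testable with no database download.

## Worked example

```sh
faersig simulate --out demo/data --seed 3
cat > demo/study.json <<'JSON'
{"drug_names": ["adefovir", "tenofovir"]}
JSON
faersig analyze --input demo/data --config demo/study.json --out demo/out
```

`demo/out/adefovir_pt_signals.tsv` then contains one row per member PT, e.g.
(columns abridged):

```
drug      level  event                   N   ROR    ROR_CI        p_value      consensus
ADEFOVIR  PT     osteoporosis            62  19.86  14.59-27.04   1.51e-49     True
ADEFOVIR  PT     bone loss                2   0.57   0.14-2.31    1            False
```

The generator planted an elevated reporting rate for this drug on
`osteoporosis`, and the pipeline recovers it: 62 deduplicated reports pair
the drug with the PT, the reporting odds ratio is ~20 with a 95% CI well
above 1, and the pair is a consensus signal; `bone loss`, left at the
background rate, stays null. `*_smq_signals.tsv` carries the group-level row
plus the four subgroup rows (male/female/younger/older), and `*_tto.tsv`
reports the onset summary with the Weibull shape, its CI and the
failure-curve class. The same API is available from Python
(`faersig.run_analysis`, `faersig.ror_estimate`, ...).

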