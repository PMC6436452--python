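# sr2norm

Normative analysis for a rapid, automated test of **spatial release from
masking** (SRM) in speech-on-speech listening. The package is aimed at
hearing researchers and audiology clinics who use the two-masker
progressive-tracking test (colocated vs ±45°-separated maskers, 20 trials
per condition) and want to interpret a *single patient's* scores without
first collecting a control group.

It provides:

- **Scoring** — 20-trial progressive tracks → TMR thresholds
  (`threshold = 10 − #correct`, dB), SRM (`colocated − separated`), and
  audiometric summaries (standard and high-frequency bilateral pure-tone
  averages, interaural asymmetry);
- **Normative regression** — per measure (colocated, separated, SRM) and run
  label (run 1, run 2, average), OLS fits of

  `predicted threshold = constant + age·β_age + PTA·β_PTA`

  with backward elimination of non-significant terms (interaction first),
  model error (RMSE of residuals, MAE optional), and a Bonferroni-corrected
  correlation screen (.05/15 → .0033);
- **Z-scoring** — `Z = (observed − predicted) / model error`, with |Z| ≥ 2
  flagging performance abnormal for the listener's age and hearing, on any
  of the nine measure × run combinations;
- **A psychometric cohort simulator** — demographically calibrated synthetic
  listeners (age–PTA structure, latent thresholds from the published
  regression coefficients, trial-by-trial Bernoulli responses through the
  actual 20-trial track) so the entire pipeline is testable end to end;
- **A CLI** — `sr2norm simulate | score | fit | zscore | band | report`.

## Worked example

Simulate a cohort the size of the original normative sample, fit all nine
normative models, and score an individual patient:

```sh
$ sr2norm simulate --n 82 --seed 7 --out cohort.csv
$ sr2norm fit --cohort cohort.csv --models models.json --summary-dir summaries
[sr2norm 0.1.0] fit 9 models (alpha=0.05, rmse) -> models.json
[sr2norm 0.1.0] summary tables (Bonferroni criterion p < 0.0033, critical |r| = 0.321) -> summaries

$ sr2norm zscore --models models.json --age 50 --pta 10 \
    --observed srm_avg=2.0 --observed separated_avg=-2.5
      measure  observed  predicted      z  flagged  extrapolated
      srm_avg       2.0      7.118 -2.311     True         False
separated_avg      -2.5     -5.262  1.497    False         False
```

Reading the output: for a 50-year-old with a bilateral standard PTA of
10 dB HL, the cohort norms predict an average-run SRM of 7.1 dB. An
observed SRM of 2.0 dB sits 2.3 model-error SDs below that prediction —
at or beyond the 2-SD criterion, so the patient is flagged as obtaining
abnormally little spatial benefit for their age and hearing. Their
separated-condition threshold (−2.5 dB TMR vs −5.3 predicted) is elevated
but within 2 SDs, so it is not flagged on its own.

`sr2norm band --models models.json --condition srm --variable pta --start 0
--stop 45 --out band.csv` writes the normative prediction line with
±1·model-error bands for plotting; `sr2norm report` Z-scores a whole cohort
CSV and lists every flagged participant with the measures that triggered
the flag.

The same operations are available as library functions
(`sr2norm.estimate_threshold`, `fit_normative_model`, `z_score`,
`flag_outliers`, `simulate_cohort`, …); the CLI is a thin shell over them.

## Cohort CSV schema

Comma-separated UTF-8 with a header row: `id`, `age`, optional `gender`,
`hearing_aid_user`, `srt_left`, `srt_right`, `retest_delay_days`, per-ear
audiogram columns `L_0.25 … L_8` and `R_0.25 … R_8` (kHz, dB HL), and the
four observed thresholds `colocated_1`, `colocated_2`, `separated_1`,
`separated_2` (dB TMR). Derived values (PTA variants, asymmetry, run
averages, SRM) are recomputed on read. A published cohort spreadsheet can
be exported to this schema and read with a `schema={canonical: actual}`
column mapping; the full column documentation lives in
`sr2norm.cohort_io.COLUMN_DOC`. Placing such an export at
`data/s1_cohort.csv` enables an additional reproduction test in the suite.

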