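# pvrank

Rank the importance of ICU physiological variables (PVs) for individual
diseases by the **leave-one-variable-out AUC drop** of held-out disease
classifiers — a decision-support aid for building monitoring checklists in
prehospital emergency care.

Given per-stay PV time series and binary disease labels, the method:

1. cleans events and assembles per-stay episodes (**etl**),
2. extracts 42 features per PV — 6 sample statistics (min, max, mean, std,
   skewness, count) on 7 time-fraction sub-sequences of each series
   (**features**),
3. fits one ridge-penalized logistic-regression classifier per disease by
   maximum likelihood and evaluates held-out ROC-AUC (**model**),
4. designs the n + 1 PV sets (all PVs, plus each single-PV deletion), reruns
   every experiment on one shared split, and ranks PVs per disease by
   `delta_p = AUC(all) - AUC(minus p)`; diseases are then compared by top-k
   ranking overlap and Kendall tau (**rank**).

Because the source ICU database is access-controlled, the package ships a
seeded synthetic cohort generator (**synth**) with *planted* disease–PV
effect sizes, so the whole pipeline — including recovery of the planted
importance order — is testable end to end.

## CLI

A self-contained synthetic run:

```sh
cat > run.yaml <<EOF
out_dir: out
seed: 7
split_seed: 1
synthetic:
  n_stays: 2000
  effects:
    D12: {Glu: 1.5, SBP: 0.6}
  sampling_rate: 8
EOF
pvrank run --config run.yaml
```

This writes `out/auc_matrix.csv` (18 PV sets × diseases), `out/rankings.csv`
(rank × disease table of PV names), per-PV `ranking_deltas.csv`, pairwise
disease-similarity matrices, and a JSON `manifest.json` with stage counts.
Reruns with the same config are bit-identical.

Individual stages: `pvrank simulate`, `pvrank etl`, `pvrank featurize`,
`pvrank train`, `pvrank rank`, `pvrank compare` (see `--help` for each).
Input tables are plain CSV: `events.csv`
(`stay_id,patient_id,variable,time_h,value,unit`), `stays.csv`
(`stay_id,patient_id,admission_id,age_years,duration_h,stays_in_admission,transferred`),
and `labels.csv` (`stay_id,D1..D24`).

## Layout

```
src/pvrank/
  catalog.py    # canonical 17-PV / 24-disease catalogs, plausible ranges
  synth.py      # seeded synthetic cohorts with planted effects + artifact injection
  etl.py        # cohort selection, event cleaning, episode assembly
  features.py   # 7-window x 6-statistic extraction, imputation, z-scoring
  model.py      # logistic MLE (Newton / L-BFGS), multinomial variant, AUC
  rank.py       # PV-set design, experiment family, AUC-drop ranking, comparison
  pipeline.py   # end-to-end orchestration with provenance manifest
  cli.py        # click CLI
```
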