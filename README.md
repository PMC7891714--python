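# nirsload

Analysis pipeline for multi-distance prefrontal fNIRS recordings of cognitive
workload, plus a synthetic cohort generator so that every stage is testable
without any recorded data.

The pipeline mirrors a surgical-training workload study design: two-wavelength
(780/850 nm) optical-density changes recorded at 8.138 Hz over 204 channels in
four source-detector separation classes (1.5, 2.12, 3.0, 3.35 cm) during
rest/task episodes, together with NASA-TLX workload scores and 6-axis motion
traces. Stages:

1. **synthetic** — deterministic channel-layout fixture and a forward
   generator mixing depth-weighted cerebral activity (HRF-convolved task
   regressor), superficial systemic oscillations (~0.1 / ~0.3 / ~1 Hz), drift,
   noise, and motion artifacts into the optical densities, with full
   component-level ground truth.
2. **preprocess** — modified Beer-Lambert inversion (DPF 5.075 / 4.64),
   zero-phase 0.01–0.5 Hz Butterworth band-pass, and windowed-SD artifact
   rejection (non-overlapping 10 s windows; reject SD > median + 4.5·MAD).
3. **features** — per-window SD of ΔHbO averaged over the retained windows of
   each task episode; optional superficial signal regression of long channels
   on the nearest 1.5 cm channel; labelled subject-episode × channel matrix.
4. **group_stats** — within-group median-split load labels, two-sample KS and
   paired Wilcoxon tests over (separation class × hemisphere × task) cells
   with Bonferroni control (α = 0.05, k = 16), and topographic interpolation.
5. **classify** — |Pearson r| feature ranking, linear SVM (C = 1) with
   repeated subject-grouped stratified 5-fold CV, accuracy-vs-feature-count
   curves, and a label-shuffling permutation null that re-runs feature
   selection per shuffle (with an optional honest in-fold selection mode).

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (simulation-backed
ones are scaled to run on one CPU in minutes); the remaining files are unit
and property tests per module.

## CLI

```sh
nirsload simulate  --config cohort.yaml --seed 1 --out cohort/
nirsload preprocess --in cohort/ --out hb/
nirsload features  --in cohort/ --out features.csv --ssr off
nirsload stats     --in cohort/ --out stats.csv --compare skill
nirsload classify  --in cohort/ --out report.json --target skill --class-cm 3.0 \
                   --reps 100 --perms 100 --seed 1
nirsload run       --config study.yaml --seed 1 --out results/
```

All constants of the analysed protocol (8.138 Hz, 0.01–0.5 Hz band, 10 s
windows, 4.5 MAD, DPFs, α = 0.05 / k = 16, 5 folds, 2000 repetitions) are the
zero-configuration defaults; a YAML config can override any of them (see
`nirsload.io.PipelineConfig`). Exit code 2 signals a validation error.

Cohorts are exchanged as plain CSV/JSON directories (`layout.csv`,
`od_<id>.csv` in long format, `motion_<id>.csv`, `tlx.csv`, `schedule.json`,
`ground_truth.json`), written with 9 significant digits and byte-reproducible
from (config, seed).

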