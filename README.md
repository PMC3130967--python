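# groupica

Group temporal ICA for multi-subject event-related EEG.

Independent component analysis decomposes EEG into source timecourses
and scalp maps, but it does not naturally support group inference:
components estimated separately per subject come back in arbitrary
order, with no guaranteed correspondence across people. This package
implements the aggregate-data solution for epoched, event-related EEG:
reduce each subject's single-trial data by whitened PCA, concatenate
the reduced data across subjects, estimate one set of temporally
independent components for the whole group, and back-reconstruct
subject-specific component timecourses and scalp maps from the stored
reduction matrices — so every subject gets the same components in the
same order.

It is aimed at EEG researchers analyzing single-trial event-related
activity across subjects, and ships with a hybrid-data simulator
(known event-related sources with controllable latency jitter, mixed
into surrogate EEG) and a reconstruction-accuracy evaluator for
validating the approach.

## The model

With `Y_i` the `Q × V` epoched data of subject `i`
(`V = samples_per_epoch × n_trials`, trial-major), per-subject
whitening/reduction `X_i = R_i⁻¹ Y_i` to `L` dimensions, and a second
PCA `G⁻¹` reducing the stacked group data to `N` dimensions,

    X = G⁻¹ [R₁⁻¹Y₁; … ; R_M⁻¹Y_M],        X = Â Ŝ  (ICA)

where `Â` is the `N × N` aggregate mixing matrix and `Ŝ` the aggregate
component timecourses. Partitioning `G` by subject gives each subject's
component patterns `G_i Â`, scalp maps `F_i G_i Â`, and timecourses
`Ŝ_i` estimated from the subject's own reduced data — per-component
regression by default, the exact inverse `(G_i Â)⁻¹ R_i⁻¹ Y_i` as an
option (see `docs/methods.md`). Reconstruction accuracy of a component
against a known source is the squared Pearson correlation R².

Implemented ICA algorithms: Infomax (stochastic natural gradient,
logistic nonlinearity), FastICA (tanh/log-cosh contrast, symmetric
decorrelation) and JADE (joint diagonalization of fourth-order
cumulants); additional algorithms can be registered as plug-ins.

## Worked example

Simulate a small group (4 datasets, 32 channels, 256 samples, 60
trials; sources S1–S3 with latency jitter of 1, 2 and 3 waveform
widths), run the group pipeline, and score it against ground truth:

```python
from groupica import simulate_group, run_group_ica
from groupica.evaluation import build_report, report_to_wide

group, truths = simulate_group(n_datasets=4, q=32, samples=256,
                               n_trials=60, master_seed=3)
result = run_group_ica(group, L=20, N=20, algorithm="infomax", seed=0)
print("components per subject:", result.subjects[0].timecourses.shape)
ra = build_report([(result, truths)])
print(report_to_wide(ra).round(3).to_string(index=False))
```

```
components per subject: (20, 15360)
algorithm  n_components  single_trial_S1  single_trial_S2  single_trial_S3  peak_S1  peak_S2  peak_S3  average_S1  average_S2  average_S3  topography_S1  topography_S2  topography_S3
  infomax            20             0.94            0.868            0.796    0.991    0.977     0.91       0.987       0.982       0.964          0.922          0.901          0.748
```

Each subject receives the same 20 components over its
256 × 60 = 15 360 concatenated samples. The columns are mean R² across
the four datasets between each true source and its matched component:
the full single-trial timecourse of the lightly jittered S1 is
reconstructed at R² 0.94, and accuracy falls monotonically with
latency jitter (S3: 0.80) — the central behavior of the group model,
since only time-locked structure is shared across subjects. Trial
averages (≈ 0.96–0.99) and per-trial peak amplitudes (≈ 0.91–0.99) —
the features most inference is based on — survive jitter much better
than the full single-trial image.

## Command line

```
groupica simulate --datasets 10 --channels 32 --trials 100 --seed 1 --out sim/
groupica run --input sim/sim00.gica --input sim/sim01.gica ... \
             --reduce 20 --components 20 --algorithm infomax --seed 2 --out results.h5
groupica evaluate --results results.h5 --truth sim/ --out report.tsv
groupica experiment --config configs/desk_scale.toml --out out/
```

`run` also reads epoched EEGLAB `.set` files (`--dialect eeglab`).
Results are HDF5 files holding the reductions, the aggregate ICA and
every subject's timecourses and scalp maps; reports are tab-separated
tables, one row per (algorithm, component count).

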