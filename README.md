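# neuroload

Hybrid EEG+fNIRS analysis of human mental workload.

Working-memory load modulates two complementary physiological signatures:
EEG band power (frontal-midline theta rises and alpha is suppressed as the
task gets harder) and the cortical hemodynamic response measured by
functional near-infrared spectroscopy (the task-evoked ΔHbO peak grows with
load up to a capacity limit).  `neuroload` implements a complete,
reproducible pipeline that turns concurrent 19-channel EEG (250 Hz) and
19-channel dual-wavelength fNIRS (8.93 Hz) recordings of a letter n-back
protocol into cross-validated workload classifications, and ships a
protocol-faithful synthetic-subject generator so the whole chain runs and
is tested without any data download.

The stages, each usable on its own:

1. **Simulation** (`neuroload.simulate`) — 40-session letter n-back runs
   (10 sessions per n ∈ {0..3}; 5 s instruction + 44 s task + 25 s rest)
   with load-dependent EEG spectra, double-gamma hemodynamics,
   physiological noise, and a latent neurovascular coupling drive.
2. **Preprocessing** (`neuroload.preprocess`) — EEG 0.5–80 Hz band-pass +
   60 Hz notch + surface Laplacian; fNIRS modified Beer–Lambert inversion
   (ΔOD(λ,t) = −log₁₀ I/I₀, [ΔHbO; ΔHbR] = (d·DPF)⁻¹ ε⁻¹ ΔOD) and
   0.01–0.5 Hz band-pass; behavioral and artifact screening.
3. **Windowing** (`neuroload.windows`) — labeled epochs of 5/10/20/25 s
   with the block-cutting rules that give 16/8/4/2 task and 5/4/2/1 rest
   windows per block.
4. **Features** (`neuroload.features`) — 873 features in 11 subgroups:
   PSD (19×8), PLV (17×4), PAC (19×4), hemispheric asymmetry (8×8), Hb
   statistics (amp/slope/std/skew/kurt × HbO/HbR × 19 + HbO–HbR corr), and
   the neurovascular NVO/NVR correlations (2×152) linking EEG band power
   at F7/F8 to each optical channel's hemoglobin course.
5. **Selection & classification** (`neuroload.selection`,
   `neuroload.evaluate`) — scikit-learn estimators: per-subject z-scoring,
   per-subgroup PCA (`SubgroupPCA`), R² ranking against the class-code
   series (`R2Selector`), and an all-pairs ECOC linear SVM
   (`PairwiseECOC`) evaluated by k-fold cross-validation with pooled
   confusion metrics (Sens/Spec/PPV/NPV).

## Worked example

Classify 3-back against rest for one synthetic subject (half-length
protocol for speed):

```python
import neuroload as nl

table = nl.run_subject(seed=1, spec=nl.ProtocolSpec(sessions_per_condition=5),
                       window_len=25.0)
print(table.n_windows, "windows x", table.n_features, "features")

for system in ("eeg", "fnirs", "hybrid"):
    rep = nl.crossvalidate(table, ["rest", "3back"], system=system,
                           k=10, seed=1)
    print(f"{system:6s} accuracy {rep.pooled_accuracy:.3f}")

rep = nl.crossvalidate(table, ["rest", "3back"], system="hybrid",
                       k=10, seed=1)
print(rep.pooled_confusion)
print(rep.metrics.round(3))
```

prints

```
60 windows x 873 features
eeg    accuracy 0.933
fnirs  accuracy 0.900
hybrid accuracy 0.967
       rest  3back
rest     19      1
3back     0     10
       Sens  Spec    PPV    NPV
rest   0.95  1.00  1.000  0.909
3back  1.00  0.95  0.909  1.000
```

60 windows is 20 rest + 10 per-condition task windows at 25 s.  EEG
discriminates better than fNIRS alone and pooling both modalities (plus
the neurovascular features) does best — the ordering the pipeline is
designed to surface; single seeds fluctuate, and the test suite asserts it
on cohort medians.  The pooled confusion matrix counts every window
exactly once as a test observation; Sens/Spec/PPV/NPV follow from it per
class.  For chance-level calibration use `partition="block"`, which keeps
overlapping windows of one block in the same fold — see `docs/methods.md`
for why that matters.

A command-line surface wraps the same stages:

```bash
neuroload simulate --subjects 1 --seed 5 --out data/
neuroload extract --events data/sub-01_events.tsv --eeg data/sub-01_eeg.tsv \
                  --nirs data/sub-01_nirs.snirf --out features.tsv
neuroload classify --table features.tsv --case rest,3back
neuroload run-all --subjects 2 --seed 7 --out runs/
```

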