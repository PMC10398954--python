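# rseeg

Resting-state EEG analysis for two-group clinical contrasts: band power,
phase-locking-value (PLV) functional networks, weighted graph metrics,
FDR-corrected group statistics, and biomarker classification.

The motivating problem is the objective, noninvasive assessment of residual
brain-rhythm abnormalities in convalescent anti-NMDA-receptor-encephalitis
patients: even after clinical recovery (negative antibody titers, modified
Rankin Scale <= 1), patients show enhanced delta/theta power over middle and
posterior sensors together with attenuated fronto-temporo-parietal phase
coupling, and the combination of spectral, network and spatial-filter
features separates patients from healthy controls in leave-one-out
cross-validation. `rseeg` implements that full analysis chain as a tested
library plus a synthetic cohort generator with known ground truth, so the
pipeline's statistical behavior (null calibration, effect recovery,
leakage-free classification) is verifiable without clinical data.

## The core quantities

For channels u, v band-passed into band sigma and given instantaneous
Hilbert phases phi(t) (the quadrant-correct angle of x + i·HT(x)):

- **absolute band power** aPSD(sigma) = sum over f in [f1, f2) of PSD(f),
  with Welch PSD (2 s Hann, 50% overlap) averaged over 5 s epochs; bands
  delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz;
- **connectivity** w_PLV = |(1/N) sum_j exp(i(phi_u(j) - phi_v(j)))| in
  [0, 1], per epoch, averaged into a 32 x 32 weighted adjacency;
- **graph metrics** — weighted clustering coefficient C (cube-root triangle
  intensity, Brain-Connectivity-Toolbox convention) and characteristic path
  length L (Dijkstra over edge lengths 1/w);
- **group statistics** — independent-sample t-tests per channel / edge /
  metric, Benjamini-Hochberg FDR within each family, significance at
  corrected p < 0.01;
- **classification** — discriminative spatial network filters (SPN; the
  generalized eigenproblem S_P v = lambda (S_P + S_C) v on class-mean
  adjacencies) fused with aPSD and C/L into a linear SVM under LOOCV, with
  accuracy = (n_PAs + n_HCs)/(N_PAs + N_HCs) x 100%, sensitivity =
  n_PAs/N_PAs x 100%, specificity = n_HCs/N_HCs x 100%.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic cohort (18 patients + 18 controls, 300 s of 32-channel
EEG at 500 Hz, seed 0). Recordings land under `scratch/`, tables under
`results/`:

```sh
python analysis/01_simulate_cohort.py   # wrote 18 patients + 18 controls
python analysis/02_preprocess_qc.py     # kept 1833/2160 epochs (84.9%)
python analysis/03_band_power.py
python analysis/04_plv_networks.py
python analysis/05_group_statistics.py
python analysis/06_classification.py
```

Representative output (seed 0):

```
patient/control grand-aPSD ratio:  delta 1.496  theta 1.564  alpha 1.053  beta 0.999  gamma 1.018
group means:        C_delta  L_delta   C_theta  L_theta
         control     0.372    3.393     0.354    3.583
         patient     0.310    3.836     0.290    4.074
delta: 15/32 channels enhanced, 266/496 edges attenuated (patients), C t=-16.1, L t=24.6
theta: 16/32 channels enhanced, 267/496 edges attenuated (patients), C t=-21.5, L t=27.8
LOOCV over 36 subjects: accuracy 100.0%, sensitivity 100.0%, specificity 100.0%
```

Reading this: patients' delta/theta grand-average power is ~1.5x controls
(the injected amplitude gain of 1.5 raises power by 1.5^2 on the designated
posterior channels, diluted by unaffected channels), the other three bands
are null; patients' networks show significantly lower clustering and longer
path length; and the fused features classify every subject correctly. The
same chain is available as a single call —
`rseeg.pipeline.run_pipeline(config, out_dir)` — driven by a validated
JSON/YAML config with a provenance record.

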