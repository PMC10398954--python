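# Methods

`rseeg` implements a resting-state EEG group-contrast pipeline of the kind
used to characterize residual brain-rhythm abnormalities in convalescent
anti-NMDA-receptor-encephalitis patients against healthy controls: spectral
power, phase-locking-value (PLV) functional networks, weighted graph
metrics, FDR-corrected group statistics, and biomarker classification.
Because clinical recordings of this kind are rarely shareable, the package
pairs the analysis chain with a synthetic cohort generator whose effect
structure is known exactly, so every stage can be validated end to end.

## Data model

Recordings are 32-channel scalp EEG (international 10/20 montage) sampled
at 500 Hz, in microvolts. Two file dialects are supported: EDF for
interchange (16-bit, exact to quantization) and a native array+json dialect
(little-endian float32 plus a JSON sidecar) that round-trips byte-exactly,
which the determinism tests rely on. Cohorts are described by a TSV
manifest (`subject_id`, `group`, `path`); the demographics of the
18-patient convalescent cohort (15 F, age 27.22 +/- 12.28, sample SD) ship
as a packaged TSV and are reproduced exactly by `summarize_demographics`.

## Preprocessing

Fixed order: re-reference -> band-pass -> segment -> reject.

* **Reference.** Common average by default. REST (reference electrode
  standardization, an approximation of a reference at infinity) is
  available; with no subject anatomy it uses a generic spherical-head
  forward model — a radial-dipole layer at 0.79 of the scalp radius inside
  a homogeneous conducting sphere, evaluated by the Legendre series for an
  interior point source, with electrode positions taken from the standard
  10/05 montage. Only the column space of the lead field enters the REST
  transform, so conductivity and scale are irrelevant. Independent
  component analysis is deliberately out of scope: it is operator-dependent
  and unverifiable without the original clinical data; the amplitude gate
  below is the testable artifact control.
* **Band-pass.** 0.5-45 Hz, zero-phase (forward-backward) elliptic SOS
  filter, order 5, 0.05 dB passband ripple, 40 dB stopband. The elliptic
  design keeps in-band sinusoid amplitude within ~1-2% right up to the band
  edges after the forward-backward pass squares the response; a Butterworth
  of practical order sags several percent near 40-45 Hz. Zero phase
  matters because the PLV stage consumes instantaneous phases.
* **Segmentation.** Non-overlapping 5 s epochs from sample zero; the
  trailing remainder is discarded.
* **Rejection.** An epoch is dropped iff any sample on any channel exceeds
  +/-90 uV *strictly* (samples at exactly 90 uV are kept; the boundary
  convention is stated because thresholds are conventionally quoted as
  "+/-90 uV" without one).

## Spectral power

Welch PSD per epoch and channel (2 s Hann windows, 50% overlap — 0.5 Hz
resolution, matching the lowest band edge), averaged across epochs.
Averaging epochs in the *time* domain before the spectral estimate would
cancel non-phase-locked resting activity, so the average is taken over
per-epoch spectra. Absolute band power (aPSD) is the sum of PSD bins inside
the band over the five canonical bands — delta 0.5-4, theta 4-8, alpha
8-13, beta 13-30, gamma 30-45 Hz — with half-open intervals `[f1, f2)` so
shared edges are counted once (gamma closes at 45). The bin-sum convention
(rather than the density integral) is used; the two differ by the constant
bin width only, which cancels in every ratio and test statistic.

## PLV networks

For band-limited signals u, v with instantaneous Hilbert phases phi_u,
phi_v, the edge weight is `w = |mean_t exp(i(phi_u - phi_v))|` in [0, 1].
The phase is the quadrant-correct two-argument angle of the analytic
signal (a plain arctangent of HT(x)/x would lose the half-plane). Per
subject and band, PLV is computed per epoch over all channel pairs and
averaged across epochs; the diagonal is zero.

Band filtering for phase extraction applies the *squared magnitude
response* of the same zero-phase elliptic band-pass in the frequency
domain, fused with the analytic-signal construction into a single FFT pair
per epoch. This is exactly the forward-backward filter's response up to
boundary handling (circular rather than reflected); 0.25 s is trimmed from
each epoch end before the PLV, which removes the boundary transients of
either variant. A `method="sos"` path (sosfiltfilt + Hilbert) is retained
and pinned to the default by an equivalence test.

A practical note on null levels: the null PLV of band-limited noise is not
the wide-band Rayleigh value `sqrt(pi)/(2 sqrt(N))` but its band-limited
analogue with roughly `2 * bandwidth * duration` effective samples — about
0.16 per 4.5 s delta epoch. Null floors in narrow bands are therefore
substantial, and epoch-averaging reduces their variance, not their mean.

## Graph metrics

Following the Brain Connectivity Toolbox conventions: weighted clustering
coefficient C with weights scaled by max(W), cube-root triangle intensity,
and the binary-degree denominator `k_i (k_i - 1)`; characteristic path
length L as the mean over nodes of the mean Dijkstra distance to the other
N-1 nodes over edge lengths 1/w, with an explicit error on disconnected
graphs (PLV graphs are almost surely complete, and an error beats a silent
convention). A `formula="strength"` variant of C divides by node-strength
terms `s_i (s_i - 1)` instead — the two denominators circulate in the
literature, so both are shipped and both are validated against brute-force
oracles; node terms with non-positive denominators contribute zero. No
sparsification or thresholding is applied.

## Group statistics

Per band, three feature families — channel aPSD maps, upper-triangle PLV
edges, and the (C, L) pair — are compared by two-sided independent-samples
Student t-tests (pooled variance; Welch optional), sign convention
patients minus controls. Each family is corrected jointly by
Benjamini-Hochberg step-up FDR; significance is adjusted p < 0.01.
Features with zero variance in both groups are flagged undefined (NaN)
rather than given an arbitrary statistic.

## SPN and classification

The discriminative spatial pattern of networks (SPN) is a CSP-style
construction on class-mean adjacency matrices: solve
`S_P v = lambda (S_P + S_C) v` and keep the k eigenvectors from each
spectral end (default k = 1, i.e. two filters per band); a subject with
adjacency W contributes the scalar `v' W v` per filter. PLV adjacencies
have zero diagonal, hence zero trace, so a bare trace-proportional ridge
cannot regularize them: the class means are given a unit self-locking
diagonal (the PLV of a channel with itself is 1), projected onto the PSD
cone, and then ridged with `1e-6 * trace / M`. This keeps the generalized
eigenvalues in [0, 1] with the expected `lambda <-> 1 - lambda` pairing
across class orderings.

Classification fuses, per band, the grand-average aPSD, C, L and the SPN
projections (2 bands x 5 = 10 features by default) into a linear SVM
(C = 1), evaluated by leave-one-out cross-validation. Everything
data-dependent — SPN filters, per-feature z-scoring, the SVM — is refit on
the training side of every fold; with 36 subjects, fitting spatial filters
on the full sample before LOOCV inflates accuracy, and the permutation
test (below) is the operational check that no leakage remains. A
`refit_per_fold=False` flag reproduces the optimistic global-fit protocol
for comparison. Performance is summarized as accuracy, sensitivity and
specificity in percent (correct patients / all patients, correct controls
/ all controls), rounded to two decimals.

## Synthetic cohorts

Each subject is synthesized in the frequency domain:

* **Background:** 1/f^beta Gaussian noise (beta = 1), 2 uV RMS, flattened
  below the 0.5 Hz corner.
* **Oscillators:** one narrowband Gaussian process per band and channel,
  Gaussian spectral envelope centered in the band with +/-3 sigma of power
  at the band edges; default RMS amplitudes 6 / 4 / 3.5 / 1.5 / 0.8 uV for
  delta-gamma. Total RMS ~8 uV — typical of average-referenced, 0.5-45 Hz
  resting EEG, and comfortably inside the +/-90 uV gate so rejection is
  driven by injected artifacts, not by the background.
* **Power effect:** patients' delta/theta amplitudes on 12 middle/posterior
  channels are multiplied by `delta_theta_gain` (default 1.5; band power
  scales with the square, verified to follow g^2 within a few percent).
* **Coupling effect:** a 10-channel fronto-temporo-parietal set shares a
  common band oscillator per band, mixed into each member with weight
  kappa (default 0.7, variance-normalized, so kappa = 1 gives PLV = 1);
  patients' effective kappa is `kappa * (1 - patient_coupling_drop)`
  (default drop 0.5). A 3-channel occipital set keeps a fixed coupling of
  0.8 in both groups: the clinical attenuation is spatially specific, and
  a preserved strong coupling anchors the max-weight scale that the BCT
  clustering coefficient normalizes by — without it, weakening the only
  strong edges *raises* patients' normalized triangle intensity and flips
  the C direction, an artifact of the normalization rather than of the
  physiology being emulated.
* **Variability:** per-channel log-normal amplitude jitter (sigma = 0.2,
  i.e. ~40% power CoV between subjects — if anything conservative relative
  to real between-subject band-power spread) and a +/-0.05 uniform jitter
  on kappa. Jitter is drawn per channel, keeping channel-wise null
  t-statistics approximately independent; real EEG also has a global
  subject amplitude factor, which this generator deliberately omits.
* **Artifacts:** Poisson-count 150 uV half-sine bursts (0.2 s), default
  2/min, on random channels — large enough to survive the band-pass and
  trip the +/-90 uV gate.

One emergent property is worth knowing about: with 10 channels carrying the
shared oscillator at high weight, the common-average reference subtracts a
noticeable fraction of that oscillator from *every* channel, so in controls
the coupled channels show mildly elevated PLV even to channels outside the
designated set; in patients the leakage is weaker. Group attenuation
therefore extends beyond the designated pairs — exactly as reference
leakage spreads strong sources in real average-referenced EEG. The
designated within-set pairs remain the strongest and the tested effect.

Per-subject seeds are `cohort_seed + subject_index` (patients first); the
draw sequence is independent of group, so neutral parameters (gain 1,
drop 0) make a patient and control from the same seed sample-identical —
the basis of the null-calibration tests.

What the generator does *not* model: volume conduction and field spread,
eye-blink/muscle artifact morphology, a subject-specific head model for
REST, global amplitude factors, or non-stationarity across the recording.
Passing tests therefore demonstrate that the pipeline recovers effects of
the injected kind at realistic SNR and sample size — not that it is robust
to every property of clinical EEG.

## Problem sizes and numerical choices

The validation suites use the study's group size (18 + 18, 300 s per
subject) for effect recovery and classification, reduced cohorts (8 + 8,
60 s) replicated 50 times for null calibration, and 100 label permutations
at 10 + 10 for the chance-level check. Networks are built in single
precision (PLV agreement with double precision is well below the
estimation noise); tolerances follow the derivations in each test (e.g.
Rayleigh means within 10-15%, graph metrics vs brute force at 1e-12).
Degenerate inputs fail loudly: constant signals have undefined phase,
disconnected graphs have undefined L, all-rejected subjects raise with the
subject id.

## Interfaces

The numbered scripts under `analysis/` are the run surface — simulate,
preprocess/QC, band power, networks, group statistics, classification —
each a thin driver over the library that writes tables under `results/`
(bulky per-subject artifacts go to `scratch/`). `rseeg.pipeline` offers the
same chain as one call (`run_pipeline`) driven by a declarative JSON/YAML
config with schema validation (`validate_config`) and a provenance record
(config hash, per-subject seeds, epoch yields, significant-feature counts)
sufficient to re-run any stage in isolation.

## Known limitations

* SPN is a reconstruction of a published idea whose algorithmic details are
  not fully specified in the secondary literature; the generalized
  eigenproblem above is the standard CSP-analogue reading.
* The Eq.-style strength-denominator clustering variant and the BCT
  degree-denominator default answer different questions on weighted graphs;
  results in this package use the BCT default unless stated.
* REST here uses a generic spherical head; with real data and available
  MRIs a subject-specific lead field is preferable.
* EDF support targets plain continuous EEG (1 s records, one range per
  channel); annotations and discontinuous files are out of scope.
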