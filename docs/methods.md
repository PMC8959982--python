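# Methods

This note describes, in the package's own terms, the model implemented
by `plvnet`: a resting-state EEG functional-connectivity pipeline that
builds phase-locking networks in the classical frequency bands,
summarizes them with node-level graph metrics, and classifies subjects
from those metrics.

## Synthetic cohort model

Because no clinical recordings ship with the package, all analyses run
on a synthetic two-group cohort with a known planted contrast.

Each subject's signal on channel `i` is a sum over five bands of
band-limited Gaussian processes plus broadband sensor noise, scaled to
a 10 µV base amplitude. A band-limited process is white Gaussian noise
filtered to the band with a 4th-order zero-phase Butterworth filter and
normalized to unit variance. Phase coupling between channels `i` and
`j` in a band is produced by a shared latent driver:

    u_i = sqrt(1 − Σ_j c_ij) · private_i + Σ_j sqrt(c_ij) · shared_ij

where `shared_ij = shared_ji` is a band-limited process common to the
pair and `c_ij ∈ [0, 1]` is the coupling coefficient (row sums must not
exceed 1 so the private term stays real). `c_ij = 0` gives independent
phases; `c_ij = 1` makes the pair's band signals identical, so their
phase-locking value approaches 1.

The default cohort has 20 subjects per group, 8 channels (FP1, FP2,
C3, C4, T3, T4, O1, O2), 80 s at 1000 Hz. Both groups couple the four
homologous pairs (FP1–FP2, C3–C4, T3–T4, O1–O2) at 0.3 in every band.
The planted contrast:

- alpha homologous coupling is 0.9 in group B (control-like) versus
  0.4 in group A (patient-like), chosen a priori so group-mean alpha
  PLV straddles the 0.71 binarization threshold;
- group A band amplitudes are scaled ×1.5 in delta and theta and ×0.6
  in alpha (slow-wave excess, alpha deficit).

Every random draw comes from a dedicated `numpy` `SeedSequence` keyed
by (cohort seed, group, subject index, band, role, channel pair), so
generation is deterministic, order-independent, and any subject can be
regenerated in isolation. Recordings round-trip through a minimal
16-bit EDF writer and are read back with MNE.

## Preprocessing

1. Common average reference.
2. Zero-phase Butterworth band-pass 0.1–30 Hz (order 8; the steeper
   broadband stage is needed to suppress 50 Hz mains below 1%).
3. Selection of the 80-s window maximizing an SNR proxy: the fraction
   of total power lying in 0.5–30 Hz, evaluated on a 1-s stride.
4. Per-channel z-scoring over the window.
5. Split into four equal 20-s segments; each segment is one
   classification sample (40 subjects × 4 segments = 160 samples).

Band-limited versions of a segment use 4th-order zero-phase Butterworth
filters for the five bands: delta 0.5–4, theta 4–8, alpha 8–13,
beta1 13–20, beta2 20–30 Hz.

## Spectral analysis

Power spectral densities use Welch's method with 2-s Hamming windows
and 50 % overlap. Band power is the trapezoidal integral of the PSD
over the band. Band ratios ∂_b = P_b / Σ P_b are convex weights
(Σ ∂ = 1) computed per sample from channel-mean powers; they both
describe the spectrum (PS features) and weight the improved multilayer
network.

## Phase-locking networks

Instantaneous phase in a band comes from a complex Morlet wavelet
(7 cycles) centered at the band midpoint frequency, computed with
`mne.time_frequency.tfr_array_morlet`; 1 s is trimmed from each end of
a segment to discard wavelet edge effects. The phase-locking value
between channels x and y is

    PLV = | mean_t exp(i (θ_x(t) − θ_y(t))) |,

which is 1 for a constant phase difference and has expectation
√π / (2 √n) for n independent phase samples. The 8×8 PLV matrix is
binarized at a threshold: edge present iff PLV > 0.71 (strict). A
threshold sweep over 0.11–0.91 (step 0.1) is provided; a network is
flagged when its edge density falls below the random-graph connectivity
bound 2 ln N / N (≈ 0.52 at N = 8).

## Node metrics

For each binarized network, four metrics per node:

- degree `d_i`;
- local clustering coefficient: triangles through `i` divided by
  `d_i (d_i − 1) / 2`;
- local efficiency: the average inverse shortest-path length within the
  subgraph induced by `i`'s neighbors (Latora–Marchiori);
- robustness: the mean degree of the network after deleting node `i`,
  normalized by N − 1 — how well connectivity survives the node's
  removal.

Small-worldness σ = (C/C_rand)/(L/L_rand) is estimated against 100
degree-preserving rewired null graphs.

A brute-force oracle (`metric_oracle`, N ≤ 12) recomputes all four
metrics by explicit triangle enumeration, Floyd–Warshall shortest
paths, and literal node deletion; the fast networkx-based route must
agree with it to 1e-12.

## Multilayer networks

The three fast layers (alpha, beta1, beta2) are combined node-wise:

- MN: unweighted sum of each metric over layers (Eq.-1 style);
- IMN: ∂-weighted sum, where ∂ are that sample's band-power ratios
  restricted to the three layers and renormalized to sum to 1
  (Eq.-2 style). With uniform weights summing over layers, IMN
  reduces to MN / n_layers checkable by construction.

## Feature conditions and classification

Eight feature conditions per sample: PS (40 channel-band powers + 5
whole-head ratios = 45 features), the five single-layer conditions
(8 nodes × 4 metrics = 32 each), MN and IMN (32 each).

Classification is 10-fold stratified cross-validation with feature
selection refit on each training fold only (no test leakage).
Selectors: ANOVA-F filter (top-k), Kolmogorov–Smirnov screening
(p < 0.001), χ², tree importances, L2 ridge weights, PCA. Classifiers:
random forest (500 trees), RBF SVM, 5-NN, Gaussian naive Bayes,
LightGBM, gradient-boosted trees, and soft/hard voting ensembles of
the three tree learners (ELTS / ELTH). The headline configuration is
Filter (k = 20) + ELTS. An optional subject-grouped CV keeps all four
segments of a subject in one fold to quantify subject-identity
leakage.

## Numerical and scope choices

- All filters zero-phase (`sosfiltfilt`); phase estimates are never
  distorted by filter delay.
- Binarization uses a strict inequality, so ties at the threshold are
  excluded.
- The EDF writer quantizes to 16-bit with a symmetric physical range;
  round-trip error is bounded by one quantization step.
- Problem sizes (8 channels, 20+20 subjects, 80 s) were chosen to keep
  the full pipeline — generation through 10-fold CV of all eight
  conditions — within a few minutes on one CPU.

## Limitations

- The cohort is synthetic; accuracies measure recovery of a planted
  contrast, not clinical validity.
- PLV is sensitive to volume conduction on real EEG; the generator has
  no such confound, so no leakage correction (e.g., imaginary
  coherence) is implemented.
- Segments of one subject appear in different CV folds under the
  default splitter, mirroring segment-level evaluation; the grouped
  splitter is provided for the stricter subject-level question.
- The small-world σ estimate is noisy for dense 8-node graphs, where
  degree-preserving rewiring has few degrees of freedom.
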