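# Methods

This note documents the models, parameter choices and numerical decisions
behind `frfteeg`, and what the synthetic test bench does and does not show.

## Signal model and preprocessing

Recordings are multichannel voltage series in microvolts at 256 Hz. The
observed signal is treated as Q = Q_EEG + Q_N: an informative component
correlated across electrodes plus artifact/noise that is not. Epochs are
2048 samples (8 s); a 32 s recording therefore yields exactly four epochs.
Windows are half-open [iL, (i+1)L) with 0-based indexing, and a trailing
remainder shorter than one epoch is dropped. Epochs whose absolute
amplitude exceeds 73.3 μV (the conventional threshold for blink/movement
interference) are excluded whole rather than clipped per sample — clipping
would distort the scatter geometry that the features measure.

### MSPCA denoising

Four steps: (1) 5-level DWT per channel, Symlet-4, symmetric boundary
extension; (2) PCA across channels on each coefficient band
(approximation and the five detail matrices), channels mean-centred,
retaining components whose eigenvalue is *strictly* greater than the mean
eigenvalue and back-projecting; (3) inverse DWT; (4) the same PCA
retention applied once more to the reconstructed time-domain channel
matrix. The mean-eigenvalue retention rule is a Kaiser-style criterion
scaled to non-unit-variance data; when no eigenvalue strictly exceeds the
mean (all equal), the leading component is kept so the output is never
empty. PCA is applied across channels (channels as variables) because the
procedure targets multivariate recordings whose information is shared
between electrodes; it therefore requires at least two channels and leaves
single-channel data untouched in the pipeline.

Projection onto retained components is non-expansive band by band, so
output energy never exceeds input energy (up to round-off); the whole
chain is linear and deterministic.

## The fast FrFT graphical transform

For an epoch of power-of-two length N and fractional order α (default
0.5), the transform runs k = 1..log2 N stages. Stage k multiplies the
signal by the chirp filter

    f_k(m) = ((m+1)/2) · exp(jπα (m − N/2)² / 2^k),   m = 0..N−1,

takes an N-point FFT, scales by K^(2^(k−1)) with K = exp(−jπα/2), and
inverse-FFTs. After the stage loop the coefficients are

    c_k = (1/N) Σ_n y(n) · exp(−jπα (n − N/2)² / N) · exp(−j2πnk/N),

an ordered complex vector whose (Re, Im) pairs form the scatter. Design
notes:

* **Filter exponent.** The stage-filter exponent uses the order α
  directly, giving a unit-modulus chirp. Inserting the complex scaling
  constant K itself into the exponent would give the filter a real
  exponential component growing like exp(π sin(πα/2)(m−N/2)²/2^k) — it
  overflows double precision already at N = 64 and concentrates all filter
  mass on a single tap at any N, collapsing the scatter to one repeated
  point. The unit-modulus form is the only reading that produces the rich
  point clouds the representation exists for; the O(N²) direct-evaluation
  oracle in the test suite pins this convention independently of the FFT
  path.
* **Per-stage FFT length** is the full signal length N at every stage; the
  stage index enters only through f_k and the scalar K^(2^(k−1)). (A
  literal per-stage length of 2^k would conflict with filtering a
  length-N signal.)
* Coefficients keep the natural DFT ordering k = 0..N−1 (no fftshift).
* Every step is linear in the signal; for α = 0 the coefficient chirp
  degenerates to 1 and c is a scaled DFT of the stage-filtered signal.
* α is exposed as a parameter (`frft.alpha`); 0.5, midway between time
  and frequency domains, is the default.

Coefficient magnitudes grow with N through the (m+1)/2 amplitude ramp
(roughly (N/2)^log2 N overall). This is a fixed, signal-independent scale
factor per (N, α): it cancels in the classifier's z-scoring and affects
the geometric features only through their documented scale degrees.

## The 34 geometric features

Computed on the ordered cloud P_i = (x_i, y_i), i = 0..N−1, with the
coordinate centre fixed at the origin (the transform centres the scatter
by construction; a centroid-based variant is available via
`features.center`). Degenerate inputs are defined, not errors: a single
point yields 0 for every length/area/angle feature, and a cloud collapsed
onto the centre has all CTM values 1.

| group | features | definition highlights |
|---|---|---|
| consecutive geometry | SCCA, SCTA, SSVL, SATP, TACR | circle areas on consecutive-point diameters; triangle areas over consecutive triples; polyline length; interior turning angles in [0, π]; triangle areas against the origin |
| circumcircles | SHCA, SDHC, SAHC | per consecutive triple, circumradius R = abc/4A (A by Heron's formula) and circumcentre; near-degenerate triples (A < 1e−12·scale²) are skipped from all three sums |
| set dispersion | SH45, SH135, AOCT, SDTC, SCRA, TDSD, ELPA | distances to y = x and y = −x; smallest enclosing octagon via support values at 45° steps; radial distance sum; per-point diagonal rectangles; Poincaré SD1+SD2 (sample std, 1/(N−1)); covariance-ellipse area π√(λ₁λ₂) |
| concentration | CTM1..CTM19 | fraction of points within radius (k/20)·r_max; non-decreasing in k, bounded in [0, 1] |

Equivariances used as test invariants: uniform scaling by s multiplies
length-type features by s and area-type features by s²; rotation about the
origin preserves SSVL, SDTC, SATP, ELPA and all CTMs; set-type features
are invariant to point order while consecutive-type features are not.

## Ensemble feature selection

Five per-column scores: information gain with 10 equal-width bins and
entropies in bits; full ReliefF (k = 10 nearest hits/misses in the
min-max-scaled full feature space, L1 distances); population variance
(1/m); a closed-form single-feature neighbourhood score — leave-one-out
soft-neighbour class purity with kernel width σ̂ = mean absolute pairwise
difference of the column — used instead of gradient-trained NCA because
the single-feature problem admits this direct form; and the absolute
point-biserial correlation with the 0/1 label (the subset-merit version of
correlation-based selection is out of scope; for a single feature against
a binary target the merit reduces to this correlation). Each scorer row is
min-max normalized to [0, 1]; a weighted mean (equal weights by default)
gives the ensemble score, and the top-K indices are selected with ties
broken toward the lower index. K = 16 by default; a "cfs" mode ranks by
the correlation filter alone, and the 16-feature subset reported as the
best configuration in the reference study ships as a loadable preset
(`REPORTED_SELECTED_FEATURES`) — its membership is not re-derived from
synthetic data.

Note on the adaptive kernel width: because σ̂ grows with class
separation, the neighbourhood score saturates near
(m/2−1)/((m/2−1) + (m/2)e^(−1/0.505)) ≈ 0.88 for balanced two-cluster
data rather than approaching 1; its null value for an uninformative
feature is the same-class fraction ≈ 0.5.

## Classifiers

All iterative kinds share: z-scoring on training statistics (stored on the
model, so test data never contributes), sigmoid output, mean binary
cross-entropy loss, full-batch gradient descent, uniform [−0.5, 0.5]
initialization from a seeded generator, and per-epoch loss history.
Optimizer, loss and init are this package's choices; the reference
hyperparameters fix only learning rate, width, activation and epochs:

| kind | architecture | lr | epochs |
|---|---|---|---|
| slnn | 50 ReLU | 0.01 | 100 |
| mlnn | 100 + 100 tanh | 0.05 | 200 |
| ffnn | 200 sigmoid | 0.1 | 150 |
| cfnn | 100 ReLU + input→output skip | 0.01 | 100 |
| rnn | Elman, 50 tanh units, one feature per time step, final state read out | 0.01 | 200 |
| grnn | kernel regression, σ = 0.5 | — | — |

The two-layer depth of `mlnn` and the feature-as-sequence presentation of
`rnn` are interpretations of named topologies without wiring diagrams. The
GRNN predicts Σ y_i w_i / Σ w_i with w_i = exp(−‖x−x_i‖²/2σ²); its
"radius" parameter (0.1) acts as a confidence floor — if the kernel-weight
sum falls below radius·m·ε (machine epsilon), the majority training class
is returned. This role for the radius is a documented guess isolated
behind the config; standard GRNN has no such parameter.

## Evaluation

Stratified k-fold (default 10): indices are shuffled per class with a
seeded generator and dealt into folds, so 240 balanced samples give
216-train/24-test folds with 12 + 12 test samples per class — plain
randomization would not guarantee that arithmetic. Metrics are computed
from per-fold confusion tables (positive class = alcoholic) and averaged;
percentages are rounded to one decimal, kappa stays on [−1, 1]. Feature
selection runs inside each training fold by default; a global
select-once-before-CV mode exists because some protocols order the steps
that way, with the leakage caveat documented here rather than silently
removed. Kruskal–Wallis screening (scipy, tie-corrected, χ² p-values)
reports H = 0, p = 1 for identical groups.

## Synthetic data

Each trial is Σ_b A(class, b)·sin(2π f_b t + φ_b) + AR(1) noise, with band
centres δ = 2, θ = 6, α = 10, β = 20 Hz and per-trial uniform phases.
Defaults: normal amplitudes (15, 8, 12, 6) μV, alcoholic at half (the
class with larger amplitudes produces the larger, more dispersed scatter;
which real class is "wider" is left as the `amplitude_ratio` parameter
since the literature descriptions conflict), AR coefficient 0.8,
innovation SD 3 μV — a stationary background of ≈5 μV SD, keeping clean
trials safely under the 73.3 μV artifact rule while injected 200 μV spikes
(probability `spike_rate`, default 0) always trip it. Multichannel trials
share the sinusoidal content with per-channel gains in [0.8, 1.2] and
independent noise, giving the correlated-signal/uncorrelated-noise
structure MSPCA assumes. 120 trials per class by default (240×34 feature
matrix).

What passing tests on this generator demonstrate: the pipeline's stages
compose correctly, preserve class contrast of the stated kind
(scale/dispersion), and are free of train/test leakage (shuffled labels
score at chance). What they do not demonstrate: performance on real EEG —
the generator has no 1/f spectrum, no volume conduction, no
non-stationarity beyond random phases, and a class difference far cleaner
than clinical data; near-perfect synthetic cross-validation accuracy is a
property of the easy task, not a clinical claim.

## Numerical choices and limitations

* Circumcircle triples with area below 1e−12·scale² are treated as
  collinear; angle cosines are clipped to [−1, 1].
* The transform requires power-of-two lengths (errors name the nearest
  valid lengths); 2048-sample epochs satisfy this by construction.
* Feature values can be numerically large for long epochs (the transform's
  deterministic scale factor); all downstream steps either normalize
  (selection, z-scoring) or are scale-aware (documented scale degrees).
* Problem sizes in the test suite and acceptance script (N = 16 oracle
  signals, 50-point clouds, 240-sample matrices, 20-replicate Monte
  Carlo) are chosen to pin each property at desk scale; the full-data
  experiment on the public UCI archive is intentionally out of scope.
* Reported reference results from the original study are not reproduced
  here; the package validates structure, arithmetic and recovery
  properties, not clinical numbers.
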