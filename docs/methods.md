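# Methods

This note documents the models implemented in `msifusion`, the choices
made where the design was genuinely open, and what the synthetic
experiments do and do not show.

## Unimodal channel model

Each modality j observes a class prototype `S_j/k` (class k) through

```
S̃_j = α_j S_j/k + N_j,   N_j ~ G(0, Ψ_j)
Ŝ_j = Φ_j S̃_j
X_j = m_j Ŝ_j + c_j
```

- **Attenuation** `α_j ∈ [0, 1]` models stimulus effectiveness: 1 is
  full strength, 0 is signal absent. Training always uses `α_j = 1`;
  attenuation is a test-time manipulation.
- **Noise** is additive Gaussian. The default is isotropic,
  `Ψ_j = σ_j² I`, one scalar variance per modality (the per-class
  variances of the study design are collapsed to their average); a full
  covariance matrix is accepted everywhere.
- **Features** are a subset of orthonormal DCT-II coefficients. The
  orthonormal dialect is deliberate: with `Φ_j Φ_jᵀ = I`, isotropic
  channel noise propagates to isotropic feature noise
  (`m² Φ Ψ Φᵀ = m²σ² I`), which makes the analytic density propagation
  trivially checkable. Coefficients are ranked by a Fisher-style
  separability score — between-class variance of the coefficient over
  pooled within-class variance, with an `ε = 1e-12` guard — computed on
  the noisy training set; the top `D_j` are kept (default 64).
- **Normalization** is one affine map per modality, fitted on the
  pooled training features so that the global min/max land exactly on
  `[a_j, b_j]` (default [0, 1]). A single pooled `(m_j, c_j)` is used
  rather than per-class constants, since the class is unknown at test
  time; test features are not clipped to the interval, which keeps the
  Gaussian propagation exact.

Because all steps are linear, the class-conditional feature density is
Gaussian with mean `m_j Φ_j S_j/k + c_j` and covariance
`m_j² Φ_j Ψ_j Φ_jᵀ`. The test suite verifies this against 10⁴ simulated
channel draws (means within 3 standard errors, covariance within 10%
relative Frobenius distance).

## Classifiers

**MLP.** One sigmoid hidden layer (default 32 units), softmax output,
cross-entropy loss, full-batch gradient descent with momentum 0.9.
Training follows a noise curriculum: stages ordered by increasing
noise, each warm-started from the previous stage's weights, each
stopped when the mean training cross-entropy falls below 0.001 or a
per-stage epoch cap is hit (5000 by default; the experiment sweeps use
1500 because the harshest stages cannot meet the threshold and would
otherwise burn the full cap). The learning rate default is 0.2: at
0.05 the loss plateaus near 2e-3 and the 0.001 stopping criterion is
unreachable in practice. Cross-entropy floors posteriors at 1e-12 so a
zero probability yields a large finite loss. Backpropagation is
verified against central finite differences to 1e-5 relative error.

**Gaussian MAP.** Per-class sample mean and covariance with shrinkage
regularization `(1−λ) Σ̂ + λ diag(Σ̂) + 1e-8 I`, λ = 0.1 by default.
Shrinkage is necessary, not cosmetic: with 64 features (128 fused) and
tens of samples per class the raw sample covariance is singular.
Posteriors are computed from log-discriminants
`g_i = ln P(X|ω_i) + ln P(ω_i)` with log-sum-exp normalization; priors
default to equal (1/K). Decisions are argmax with ties to the lowest
class index.

## Fusion architectures

**FI** concatenates normalized unimodal features (fixed modality order:
auditory, visual). The FI-MAP covariance is the full `D × D` matrix of
within- and cross-modality blocks, estimated empirically from the
fused training vectors — the study gives no estimator for the
cross-covariance blocks, and the empirical fit also captures any
shared noise across modalities. With independent channel noise the
off-diagonal blocks vanish (tested by Monte Carlo); with deliberately
shared noise they converge to the shared variance (tested against the
closed form).

**DI-MLP** feeds the concatenated unimodal posterior blocks (dimension
`K·J`) to a second-stage MLP trained with the same curriculum.

**DI-MAP** fuses hard unimodal decisions with the confusion-product
likelihood. Confusion matrices are *model-based*: for each operating
condition (σ², α) the fitted class means are attenuated around the
normalizer intercept, perturbed with the propagated noise covariance
`m²σ² I`, classified, and counted (300 draws per class, Laplace
smoothing 1). Estimating confusions by raw counting instead — on the
training set or on a held-out set of the study's size (10 stimuli per
class per level) — is too coarse at desk scale: the training-set
estimate is near-identity because the MAP classifier is nearly perfect
in-sample, and a 100-sample held-out estimate puts ~1 count per
off-diagonal cell, so the product rule has no structure to exploit.
The model-based estimate is exact in the limit of the model being
true, costs no stimuli, and is matched to the operating condition.
Exhaustive enumeration over all `K^J` decision vectors verifies the
product posterior and the normalization `Σ_Z P(Z|ω_k) = 1`.

The confusion-product rule can only beat the best unimodal classifier
when unimodal confusions are *concentrated and modality-specific*:
when modality 1 errs toward an acoustically confusable class, modality
2's differently-structured confusion resolves the tie. With
unstructured (near-uniform) confusions its gain is provably small.
This is why the auditory generator builds class pairs sharing a
spectral band (within-pair zero-lag correlation ≈ 0.8, across ≈ 0.1):
real spoken digits have exactly this concentrated pairwise confusion
structure, and a generator with mutually orthogonal prototypes would
misrepresent the data regime the DI model was designed for. Glyph
images carry their own, different, similarity structure for free.

## Synthetic stimuli

- Visual: digits 0–9 rendered from fixed 5×7 dot-matrix bitmaps,
  nearest-neighbour scaled to the target resolution (default 64×64)
  and thresholded at 0.5. Deterministic; all pairs distinct.
- Auditory: per class, a shared-band fundamental and second harmonic
  plus a class-unique harmonic and chirp direction under a Hann
  envelope, peak-normalized to 0.9; 4000 samples at 8 kHz by default.
  Phases are drawn once from the prototype seed, so generation is
  fully reproducible. File-loaded audio is tail-truncated or
  zero-padded to the channel's raw dimension.
- Datasets: `α · prototype + G(0, σ² I)` per stimulus, exactly
  `n_per_class` stimuli per class, bit-reproducible from the seed.
  Congruent multimodal sets share one label ordering across modalities.

What the generator does **not** emulate: speech segmentation and
duration variability, non-Gaussian and correlated sensor noise,
within-class prototype variability (every class has a single exemplar),
and natural image statistics. Passing tests therefore demonstrate the
architectural properties of the fusion models under the assumed
(linear-Gaussian, single-prototype) stimulus model, not performance on
real recordings.

## Experiment protocol

- **Study conditions** (defaults): K = 10, J = 2, 64 features per
  modality, 10 training + 10 test stimuli per class per noise level,
  5 paired noise levels, 5 replicate seeds, training at α = 1,
  equal priors.
- **Noise pairing.** A given variance hurts the two modalities very
  differently, so the sweep uses (A, V) pairs calibrated to equal
  unimodal validation accuracy, per classifier family (the MAP family
  tolerates different variances than the MLP family). Pass 1 trains a
  validation classifier per grid variance and inverts the monotone
  accuracy envelope at targets spanning 0.9 down to 0.2. Pass 2
  re-measures the curve through systems trained with the sweep's own
  protocol — curriculum MLPs and pooled MAP are substantially more
  noise-robust than single-variance classifiers — and re-inverts the
  targets, blending old and new variances geometrically (weight 0.5)
  because the training conditions move with the ladder and a full
  update overshoots the calibration fixed point.
- **Sweep.** Per replicate seed, all eight systems are trained once on
  congruent stimuli spanning every rung, then tested on freshly
  generated stimuli at each rung (and, for the attenuation experiments,
  at α < 1 with training unchanged).
- **Significance.** Every system is evaluated at the same rungs with
  the same replicate seeds, so rung and replicate are blocking factors:
  accuracies are analyzed with a two-way ANOVA
  (`accuracy ~ system + rung + replicate`) and Tukey HSD contrasts on
  the system factor via the studentized range with the blocked error
  variance. A one-way analysis that treats per-rung accuracies as
  exchangeable replicates was considered and rejected: with rungs
  spanning accuracy 0.9→0.2 the rung factor contributes roughly
  twenty times the residual variance, which buries even a 0.2 mean
  multimodal gain — no realistic effect could reach significance
  under it, whereas the blocked design is the standard analysis for
  curves sharing an x-axis. The F statistic is cross-checked against a
  within-block permutation oracle in the tests. Degenerate
  (zero-variance) accuracy data yields NaN p-values with a warning
  flag.

## Numerical choices and degenerate inputs

- Child seeds derive from a master seed through `SeedSequence` and stay
  below 2³¹.
- Zero noise variance short-circuits sampling (exact copies); zero
  attenuation produces exact zero signals, and classification then
  degenerates to a constant decision, i.e. chance accuracy.
- The normalizer refuses a degenerate (constant) feature range; the
  coefficient ranking guards zero within-class variance with ε.
- Covariance inputs are validated for symmetry and positive
  semidefiniteness (tolerance 1e-10).
- Confusion smoothing keeps every entry positive so the DI-MAP product
  never collapses to an all-zero likelihood; unsmoothed estimates raise
  a targeted error if they do.

## Problem sizes

Unit tests run on a 4-class miniature (256-sample audio, 16×16 images,
12 features). The end-to-end sweep and the acceptance script use the
full study conditions above; one family's calibrate-train-test cycle
takes under a minute on one CPU, dominated by MLP curriculum epochs.

## Known limitations

- Single prototype per class: within-class variability is entirely
  noise-driven, so absolute accuracies are optimistic relative to real
  data; the multimodal-vs-unimodal *differences* and trends are the
  meaningful output.
- The calibration refinement is one damped iteration, not a solved
  fixed point; realized sweep accuracies track the nominal targets to
  within a few points, not exactly.
- DI-MAP's gain depends on the confusion structure of the stimuli; on
  data with near-uniform confusions it degenerates to roughly the best
  unimodal accuracy, which is a property of hard-decision fusion, not
  an implementation artifact.
- Spatial- and temporal-offset attenuation rules are out of scope; the
  scalar α is the only effectiveness control.
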