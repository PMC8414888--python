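# Methods

`restbci` links intrinsic properties of short resting-state EEG
recordings to a subject's subsequent two-class motor-imagery (MI)
decodability. This note describes the models and procedures each stage
implements, the parameters that matter, what the synthetic cohort does
and does not emulate, and the numerical choices made where the design
was genuinely open.

## Pipeline overview

For each subject the pipeline consumes one 60-s eyes-open (REO) and one
60-s eyes-closed (REC) resting recording plus a labelled MI session
(56-channel 10-10 montage, 160 Hz), and produces:

1. **Resting features** — band-pass 0.1–55 Hz (zero-phase FIR), 30
   non-overlapping 2-s epochs in randomised order, then per channel and
   epoch: 12 spectral features, sample entropy, permutation entropy,
   and the recurrence measures DET, LAM and MRT. Subject-level values
   are the mean over epochs (the SD is retained as a secondary
   aggregate).
2. **MI decodability** — filter-bank common spatial patterns with a
   quadratic classifier under 5×5-fold stratified cross-validation;
   the subject's score is the mean fold accuracy (and the maximum over
   decoders if several are registered).
3. **Performance grouping** — accuracies are split into low /
   intermediate / high at two thresholds derived from a chance-level
   confidence interval, and rescaled to Cohen's kappa,
   κ = (p_a − p_c)/(1 − p_c) with p_c = 0.5.
4. **Association screening** — per (condition, feature, channel): a
   Kruskal–Wallis omnibus test across the three groups, Welch t
   contrasts ("others vs low", "high vs others"), and an OLS regression
   of kappa on the feature (slope, Pearson r). A record is *significant*
   iff the Bonferroni-adjusted omnibus p < 0.01 **and** |r| > 0.3.

## Feature definitions

**Spectral (12 per channel).** Single-segment Hamming periodogram per
2-s epoch (frequency resolution 0.5 Hz), restricted to 4–50 Hz. Median
frequency: smallest grid frequency at which cumulative power reaches
half the total (the ≥-half convention; ties go to the lower
frequency). Spectral Shannon entropy: −Σ q ln q over the normalised
4–50 Hz bins (natural log). Band powers are bin means over theta 4–8,
alpha 8–13, low beta 13–20, high beta 20–30 and gamma 30–50 Hz with
half-open [low, high) edges so shared boundaries count once; the
C(5,2) = 10 pairwise ratios (lower band in the numerator) complete the
12. The fifth (gamma) band makes "10 ratios from all possible pairs"
arithmetically consistent with a 50 Hz analysis bound; the scheme is
configurable.

**Sample entropy.** SE(m) = −ln(P_{m+1}/P_m) with template matching
under the Chebyshev norm, self-matches excluded, both template lengths
counted over the same start-index range. Defaults m = 1, r = 0.2 × the
epoch's SD — the standard tolerance convention; an absolute-r mode is
available. With the SD convention the measure is invariant to offset
and positive rescaling.

**Permutation entropy.** Ordinal motifs of length D = 3 at delay
τ = 1; Shannon entropy of the motif distribution normalised by ln(D!),
hence in [0, 1]. Ties rank by earlier index (stable order).

**Recurrence quantification.** Each epoch is z-normalised; the
recurrence matrix is R_ij = Θ(ε − |x_i − x_j|) with ε = 0.3, maximum
norm, no time-delay embedding (emb_dim = 1; both embedding parameters
are exposed), line of identity included, Θ(0) = 1. DET and LAM are the
fractions of recurrence points on diagonal and vertical lines of
length ≥ 2; MRT is the mean length of white vertical gaps, reported as
missing for a recurrence-saturated plot (no gaps) rather than 0. Runs
touching the matrix border count at their observed length. A constant
epoch (z-normalisation undefined) yields missing values for all three.
With the minimal line length at its default 2, "points on lines of
length ≥ 2" equals "recurrent points that are not isolated along the
line direction", which the implementation exploits as a vectorised
fast path; a general run-length histogram path handles other minimal
lengths, and the two are cross-checked against brute-force run
scanning in the tests. One consequence of the run-length definition
worth noting: an all-ones matrix has DET = (N²−2)/N², not 1, because
its two corner cells lie on diagonals of length 1.

## FBCSP + QDA decoding

MI trials are 2-s fixation + 4-s task; the decoded epoch is the 4-s
task window minus the per-channel fixation mean. Nine zero-phase 4-Hz
band-pass copies (4–8 … 36–40 Hz) are computed per trial. Per band,
trial covariances are trace-normalised, averaged within class, ridge
stabilised (λ = 10⁻⁶·tr/n_ch), and the generalized eigenproblem
S₁W = (S₁+S₂)WD is solved; the feature vector concatenates the log
normalised variances along the first and last m = 2 filter columns of
every band (36 entries, all ≤ 0). Classification uses a per-class
Gaussian model whose covariances are shrunk toward their diagonal
(coefficient 0.1) — necessary because a training fold holds ~34 trials
per class against 36 features. Cross-validation is stratified 5-fold,
repeated 5 times; spatial filters and the classifier are fitted inside
each training fold only (a deliberately leaky variant exists solely so
the tests can demonstrate the inflation leakage causes). Mean accuracy
is exactly invariant to a global gain; per-channel gains perturb the
per-trial trace normalisation, so channel-wise invariance is only
approximate.

The decoder registry holds FBCSP alone; the interface accepts
additional decoders (e.g. convolutional networks), whose outputs would
enter the per-subject maximum.

## Chance bounds and grouping

For N subjects with mean accuracy X̄, p̃ = (NX̄+2)/(N+4) and
CI = p̃ ± √(p̃(1−p̃)/(N+4))·z_{1−α/2}. At N = 104, X̄ = 0.5, α = 0.05
the upper bound is 0.594. Evaluating the same expression at α = 0.01
gives 0.624, not the 0.658 conventionally used as the high-performance
threshold; `group_thresholds` reports the formula value, while
`assign_groups` defaults to the reference pair (0.594, 0.658) as
overridable thresholds. Boundary values join the higher group
([0.594, 0.658) is intermediate). Because each subject's accuracy is
an average over many trials while the interval is built for the
cohort-mean scale, the bound is conservative: simulated chance-level
cohorts land above the α = 0.05 bound at a rate between α/8 and α.

## Statistical screening

Subjects with missing aggregated features are dropped pairwise per
record and the surviving count logged. The Bonferroni family defaults
to the channels of one (condition, feature) pair (56 tests); a
stricter global family (all channels × features within a condition) is
available. The omnibus gate is Kruskal–Wallis (the groups are small
and unequal); a classical F-test is not separately implemented. Welch
contrasts use the Welch–Satterthwaite degrees of freedom with the
better-performing side minus the comparison side, so features that
increase with performance get positive t in both contrasts.

## The synthetic cohort

The generator provides a ground-truth cohort in which every downstream
stage is testable. Band-limited sources are mixed onto channels by
smooth unimodal weight maps (peak 1, Gaussian decay over the subset
index); the background is per-channel AR(1) noise with coefficient
0.95 (1/f-like). Numbers below refer to the defaults.

**Frontal theta.** The theta source is a nonsinusoidal periodic wave —
a 4 Hz fundamental plus a phase-locked 8 Hz partial at amplitude 0.7,
so all harmonics stay inside 4–8 Hz — whose *regularity* parameter
controls how sustained and phase-stable the rhythm is: at 1 the
envelope is constant and the phase fixed (a pure periodic
oscillation); toward 0 the phase diffuses (smoothed random walk) and
the amplitude waxes and wanes with an infra-slow (0.2–0.8 Hz) burst
envelope, the way irregular resting theta does. This construction was
chosen after the more obvious one — mixing a sinusoid with band-limited
noise — proved unable to drive the recurrence measures coherently: at
embedding dimension 1 a pure sinusoid's recurrence plot carries thin
mirror (anti-diagonal) lines, leaving its DET *below* that of
narrow-band noise, and the additive mixture responds non-monotonically
in MRT. With the burst/diffusion model, epoch-averaged DET and LAM
increase and MRT decreases monotonically in regularity (a rank
correlation test over 21 levels is part of the suite). Theta amplitude
is kept high (theta_level ∈ [2.8, 3.8]) so frontal channels are
theta-dominated and amplitude confounds on the z-normalised recurrence
measures stay small, while the θ/β ratios still track theta level.
Frontal-channel band ratios are consequently larger than typical real
EEG values; the screening statistics only use their ordering.

**Eyes closed.** REC recordings add an occipito-parietal alpha source
enlarged 3× (alpha dominance). The cohort draws the REC theta
parameters from an independent stream with the same marginals, so the
planted link below exists only in REO — the configuration the
screening stage's specificity is tested against.

**Motor imagery.** Trials are 2-s fixation + 4-s task. Sensorimotor mu
(8–13 Hz) and beta (13–30 Hz) sources sit on the left and right halves
of the central strip at 0.35× the subject's resting alpha/beta
amplitudes (sensorimotor rhythms are weaker than the occipital alpha
generator); during the task window the hemisphere contralateral to the
imagined hand is suppressed in power by (1 − erd_strength). Fixation
windows carry no class effect, which the tests verify by decoding them
at chance. With the defaults, mean CV accuracy rises from ~0.52 at
erd_strength 0 to ~1.0 at 0.9; 21 trials per class (≈ 3 runs × 7)
matches the public corpus's scale.

**The planted link.** A standard-normal latent g per subject drives
theta level and regularity through the normal CDF; decodability is
erd_strength = squash(ρ·g + √(1−ρ²)·e) (Gaussian copula,
erd ∈ [0.05, 0.95]). The empirical corr(theta_level, erd_strength)
approaches ρ as the cohort grows (monotone squashing attenuates the
Pearson correlation only slightly; e.g. ≈ 0.89 at ρ = 0.9). Because
every resting feature depends on the decodability latent only through
g, ρ is a hard ceiling on any feature–kappa correlation — a fact to
keep in mind when judging screening power at small n: at ρ = 0.6 and
n = 40 the Bonferroni-adjusted omnibus gate (raw p < 1.8 × 10⁻⁴ over a
56-channel family) fires only in a minority of realisations, while the
|r| > 0.3 arm with the correct sign pattern (θ/Hβ and DET positive,
MRT negative over frontal channels) is recovered robustly; the
recovery tests assert the latter.

**What the generator does not emulate.** No volume-conduction head
model (mixing weights are schematic), no ocular/muscle artifacts, no
non-stationary drifts or impedance changes, no inter-channel
correlation structure beyond the shared sources, and accuracy near
ceiling for the strongest planted effects. Passing tests therefore
establish that the pipeline recovers a known ground truth under clean
conditions, not that the features predict performance in real
recordings.

## Numerical choices and conventions

- Zero-phase filtering: Hamming windowed-sinc, order ≈ 3.3·fs/ΔF
  (transition 1 Hz for the 0.1–55 Hz filter, 3 Hz for the 4-Hz filter
  bank so the kernel stays short relative to a 4-s trial), applied
  forward-backward via one FFT convolution with the combined kernel;
  odd-reflect padding of one kernel length. Forward-backward
  application doubles stopband attenuation and squares the passband
  ripple (passband idempotence is tested at <2%).
- "Randomly segmented" resting epochs: the contiguous non-overlapping
  partition presented in randomised order (60 s / 2 s = exactly 30); a
  random-start, possibly overlapping mode is available by flag.
- Heavy pairwise computations (sample entropy, recurrence measures)
  accept float32 input and preserve it; the pipeline featurises epochs
  in single precision. The per-series reference paths are float64 and
  the suite checks batch/single agreement.
- Seeds: every stage derives child seeds from the master seed
  (SeedSequence); identical configurations produce byte-identical
  output tables.
- Degenerate inputs: zero-variance epochs yield missing feature
  values, zero band power yields missing ratios, and missing subject
  values are dropped pairwise in the statistics with counts logged.

## Problem sizes

The analysis scripts run the full study conditions (40 subjects, 30
epochs per condition, 21 trials per class). The test suite's
end-to-end recovery runs use 15 epochs per condition — epoch count
only affects the (already small) subject-level feature standard error
— and the miniature pipeline contract test uses 3 subjects with 10
epochs and 6 trials per class.

## Known limitations

- EDF ingest (public motor-imagery corpus dialect) is supported via
  MNE, but there is no EDF writer; the cohort persists as
  float32 arrays + JSON sidecars + a CSV manifest.
- The decoder registry contains only FBCSP; reported "maximum over
  decoders" equals the FBCSP score until more decoders are plugged in.
- The chance-bound formula is applied with N = number of subjects, as
  is conventional in this literature, although its derivation concerns
  trial counts; the grouping calibration test documents the resulting
  conservatism.
- Single-process execution; a 40-subject full run takes a few minutes
  on one core.
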