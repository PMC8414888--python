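# restbci

Some people can steer a motor-imagery brain–computer interface (BCI)
with ease; others never reach usable accuracy ("BCI inefficiency").
`restbci` is an analysis pipeline for a question that matters to anyone
screening BCI users: **can a minute of task-free resting EEG predict how
well a subject will subsequently be decoded in a two-class motor-imagery
task?** It targets researchers in EEG/BCI signal analysis who want the
whole chain — feature extraction, decoding, performance grouping and
association screening — as tested, reusable, seeded code.

## What it computes

*Resting features* (per channel, averaged over 30 × 2-s epochs of a
band-passed 0.1–55 Hz recording, eyes open and eyes closed):

- **Spectral (12):** median frequency; spectral Shannon entropy
  −Σ qₖ ln qₖ over the 4–50 Hz periodogram; the 10 pairwise band-power
  ratios of θ (4–8), α (8–13), Lβ (13–20), Hβ (20–30), γ (30–50 Hz).
- **Sample entropy:** SE(m) = −ln(P_{m+1}/P_m), m = 1, r = 0.2·SD,
  Chebyshev matching, self-matches excluded.
- **Permutation entropy:** Shannon entropy of ordinal motifs (D = 3,
  τ = 1) normalised by ln(D!) ∈ [0, 1].
- **Recurrence quantification:** from R_ij = Θ(ε − |x_i − x_j|) on the
  z-normalised epoch (ε = 0.3, maximum norm): determinism **DET** and
  laminarity **LAM** (fraction of recurrence points on diagonal /
  vertical lines of length ≥ 2) and mean recurrence time **MRT** (mean
  white vertical gap).

*Decodability:* filter-bank CSP (nine 4-Hz bands, generalized
eigenproblem S₁W = (S₁+S₂)WD, log-variance features with m = 2 pairs)
plus a diagonal-shrinkage QDA, under 5×5-fold stratified
cross-validation with fold-internal fitting.

*Grouping:* the chance-level confidence bound
p̃ ± √(p̃(1−p̃)/(N+4))·z_{1−α/2} with p̃ = (NX̄+2)/(N+4) — 0.594 at
N = 104, X̄ = 0.5, α = 0.05 — splits subjects into low / intermediate /
high; accuracies convert to Cohen's kappa κ = (p_a − p_c)/(1 − p_c).

*Screening:* per (condition, feature, channel), Kruskal–Wallis omnibus
across groups, Welch post hoc contrasts (others vs low, high vs
others), OLS slope and Pearson r of kappa on the feature; significant
iff Bonferroni-adjusted p < 0.01 **and** |r| > 0.3.

A forward-model synthetic cohort (`restbci.cohort`) generates resting
and motor-imagery recordings in which frontal-theta character and
decodability share a planted latent correlation ρ, so the full chain is
testable without any external data. Real recordings in the public EDF
motor-imagery corpus layout can be ingested via `restbci.pipeline.ingest_edf`
(requires `mne`), but nothing depends on them.

## Worked example

Feature extraction on one synthetic subject:

```python
from restbci import (SubjectProfile, generate_resting_recording,
                     bandpass_zero_phase, FilterSpec, segment_resting,
                     sample_entropy, permutation_entropy,
                     recurrence_matrix, determinism, mean_recurrence_time)

profile = SubjectProfile(subject_id=0, theta_level=3.3, regularity=0.9)
rec = generate_resting_recording(profile, "REO", duration_s=60.0, seed=1)
epochs = segment_resting(bandpass_zero_phase(rec, FilterSpec(0.1, 55.0)), seed=1)
x = epochs.epochs[0, rec.layout.names.index("Fz")]

print(sample_entropy(x), permutation_entropy(x))
rp = recurrence_matrix(x)
print(determinism(rp), mean_recurrence_time(rp))
```

prints (rounded)

```
0.672 0.685
0.87 13.77
```

— a strongly regular theta subject: low entropies, DET near 0.9, short
recurrence times.

The full study is the numbered scripts under `analysis/` (a 40-subject
cohort with planted ρ = 0.6, seed 7; each regenerates its inputs
deterministically, so they also run standalone):

```
cd analysis
python 01_simulate_cohort.py     # realised corr(theta, erd) = +0.564
python 02_resting_features.py    # 76160 subject-level feature records
python 03_decode_mi.py           # cohort mean accuracy 0.750 (0.418 .. 1.000)
python 04_performance_groups.py  # groups: 24 high / 2 intermediate / 14 low
python 05_associations.py
```

The last script prints the study's headline table — the strongest
frontal eyes-open association per feature:

```
theta/hbeta    F2  r=+0.47  slope=+0.00123  kw_p=8.11e-03  p_adj=0.454
det            F3  r=+0.52  slope=+23       kw_p=5.93e-03  p_adj=0.332
lam            F3  r=+0.51  slope=+18.2     kw_p=9.72e-03  p_adj=0.544
mrt           AF3  r=-0.52  slope=-0.443    kw_p=1.06e-02  p_adj=0.594
shanen         Fz  r=-0.51  slope=-0.65     kw_p=8.76e-03  p_adj=0.491
eyes-closed records passing the screen: 0 of 952
```

Subjects with regular, sustained frontal theta are the decodable ones:
θ/Hβ, DET and LAM associate positively with kappa, MRT and spectral
entropy negatively, and the eyes-closed condition — whose theta is
decoupled from decodability by construction — shows nothing. With 40
subjects the |r| ≈ 0.5 associations clear the correlation screen but
not the 56-channel Bonferroni gate (p_adj ≈ 0.3–0.6); that gate needs
cohorts of roughly a hundred subjects, which is exactly the regime the
grouping thresholds above come from.

A `restbci` console script wraps the same stages
(`restbci run-all --n-subjects 10 --out-dir results/demo`,
`restbci thresholds --n-subjects 104`, …).

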