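"""Synthetic EEG cohort with a planted resting-state -> decodability link.

The generator emulates the structure of a public motor-imagery corpus:
per subject one 60-s eyes-open (REO) and one 60-s eyes-closed (REC)
resting recording plus a session of labelled two-class motor-imagery
trials (2-s fixation + 4-s task), sampled at 160 Hz on a 56-channel
10-10 montage.

Signal model
------------
Band-limited oscillatory sources are mixed onto channels through smooth
unimodal weight maps over named channel subsets, on top of per-channel
first-order autoregressive background noise (AR coefficient 0.95 by
default, giving a 1/f-like spectrum).  The frontal theta source is a
``regularity``-weighted mixture of a pure sinusoid and 4-8 Hz filtered
noise, so the subject-level ``regularity`` knob directly controls the
determinism/laminarity/recurrence-time measures computed downstream.
During motor-imagery task windows, mu (8-13 Hz) and beta (13-30 Hz)
power over one lateralised half of the central strip is suppressed by a
factor ``1 - erd_strength`` (contralateral to the imagined hand),
emulating event-related desynchronisation.

Cohort model
------------
A shared standard-normal latent factor per subject drives theta level
and theta regularity; decodability (``erd_strength``) is a monotone
squashing of a second latent correlated with the first at a chosen
``rho`` (Gaussian copula).  The eyes-closed recording draws its theta
parameters from an *independent* stream with the same marginals, so the
planted link lives only in the eyes-open condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

__all__ = [
    "ChannelLayout",
    "SubjectProfile",
    "EffectSpec",
    "Recording",
    "default_layout",
    "generate_resting_recording",
    "generate_mi_session",
    "draw_profiles",
    "generate_cohort",
]

# BCI2000 64-channel 10-10 montage order, minus the eight peripheral
# channels (AF7/8, FT7/8, T9/10, Iz, Oz) routinely discarded for motion
# artefacts, leaving 56.
_MONTAGE_64 = [
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]
EXCLUDED_CHANNELS = ("AF7", "AF8", "FT7", "FT8", "T9", "T10", "Iz", "Oz")

_FRONTAL = [
    "Fp1", "Fpz", "Fp2", "AF3", "AFz", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
]
_CENTRAL = [
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
]
_OCCIPITO_PARIETAL = [
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names plus the subsets sources project onto."""

    names: tuple[str, ...]
    frontal_set: tuple[str, ...]
    central_set: tuple[str, ...]
    occipito_parietal_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("layout has no channels")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel labels must be unique")
        for subset in (self.frontal_set, self.central_set,
                       self.occipito_parietal_set):
            missing = set(subset) - set(self.names)
            if missing:
                raise ValueError(f"subset channels not in layout: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def indices(self, subset: tuple[str, ...]) -> np.ndarray:
        pos = {name: i for i, name in enumerate(self.names)}
        return np.array([pos[name] for name in subset], dtype=int)


def default_layout() -> ChannelLayout:
    """The 56-channel montage (64-channel 10-10 minus 8 peripherals)."""
    names = tuple(ch for ch in _MONTAGE_64 if ch not in EXCLUDED_CHANNELS)
    return ChannelLayout(
        names=names,
        frontal_set=tuple(_FRONTAL),
        central_set=tuple(_CENTRAL),
        occipito_parietal_set=tuple(_OCCIPITO_PARIETAL),
    )


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters for one subject.

    Amplitudes are in arbitrary units (the downstream features are scale
    invariant); ``regularity`` is the fraction of theta-source *power*
    carried by a pure periodic oscillation; ``erd_strength`` is the
    fractional task-related power suppression in [0, 1].
    """

    subject_id: int
    theta_level: float = 1.0
    alpha_level: float = 1.0
    beta_level: float = 0.5
    regularity: float = 0.5
    erd_strength: float = 0.5
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_strength <= 1.0:
            raise ValueError("erd_strength must be in [0, 1]")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must be in [0, 1]")
        for name in ("theta_level", "alpha_level", "beta_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")


@dataclass(frozen=True)
class EffectSpec:
    """Cohort-level description of the planted effect.

    ``rho`` is the latent (copula) correlation between the theta factor
    and the decodability factor across subjects.
    """

    rho: float
    n_subjects: int
    seed: int
    erd_range: tuple[float, float] = (0.05, 0.95)
    theta_range: tuple[float, float] = (2.8, 3.8)
    regularity_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")


@dataclass
class Recording:
    """One subject/condition multichannel signal.

    ``annotations`` is a list of ``(onset_sample, label)`` event marks;
    for motor-imagery sessions the onset marks the task cue (end of the
    2-s fixation) and the label is the trial class ("L"/"R").
    """

    data: np.ndarray  # [channels x samples]
    fs: float
    layout: ChannelLayout
    condition: str  # "REO" | "REC" | "MI"
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be [channels x samples]")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("channel count does not match layout")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# source and noise primitives


def _unimodal_weights(n: int) -> np.ndarray:
    """Smooth weight map over an ordered subset: peak 1 at the centre,
    Gaussian decay with inter-channel index distance."""
    if n == 1:
        return np.ones(1)
    idx = np.arange(n, dtype=float)
    centre = (n - 1) / 2.0
    width = max(n / 3.0, 1.0)
    return np.exp(-0.5 * ((idx - centre) / width) ** 2)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (FFT-domain mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs <= high)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               coeff: float) -> np.ndarray:
    """Per-channel AR(1) noise with unit marginal variance."""
    drive = rng.standard_normal(shape) * np.sqrt(1.0 - coeff**2)
    return signal.lfilter([1.0], [1.0, -coeff], drive, axis=-1)


def _theta_source(rng: np.random.Generator, n: int, fs: float,
                  regularity: float, freq: float = 4.0,
                  harmonic_amp: float = 0.7,
                  phase_diffusion: float = 4.0) -> np.ndarray:
    """Unit-variance frontal theta source with tunable regularity.

    The carrier is a nonsinusoidal theta wave — a ``freq`` fundamental
    plus a phase-locked partial at ``2 freq`` (frontal theta is
    characteristically nonsinusoidal) — so every harmonic stays inside
    the 4-8 Hz band.  ``regularity`` controls how sustained and
    phase-stable the rhythm is: at 1 the envelope is constant and the
    phase fixed (a pure periodic oscillation); toward 0 the phase
    diffuses (smoothed random walk) and the amplitude waxes and wanes
    in infra-slow bursts, the way irregular resting theta does.
    """
    t = np.arange(n)
    walk = np.cumsum(rng.standard_normal(n)) / np.sqrt(n)
    if n > 81:
        walk = signal.savgol_filter(walk, 81, 2)
    arg = (2 * np.pi * freq * t / fs + rng.uniform(0, 2 * np.pi)
           + (1.0 - regularity) * phase_diffusion * 2 * np.pi * walk)
    carrier = np.sin(arg) + harmonic_amp * np.sin(2 * arg + np.pi / 2)
    carrier /= np.sqrt((1.0 + harmonic_amp**2) / 2.0)
    slow = np.abs(_band_noise(rng, n, fs, 0.2, 0.8))
    env = regularity + (1.0 - regularity) * slow
    x = carrier * env
    sd = x.std()
    return x / sd if sd > 0 else x


def _project(source: np.ndarray, layout: ChannelLayout,
             subset: tuple[str, ...], out: np.ndarray) -> None:
    idx = layout.indices(subset)
    w = _unimodal_weights(len(idx))
    out[idx] += w[:, None] * source[None, :]


# ---------------------------------------------------------------------------
# recordings


def generate_resting_recording(
    profile: SubjectProfile,
    condition: str,
    duration_s: float = 60.0,
    fs: float = 160.0,
    layout: ChannelLayout | None = None,
    seed: int = 0,
    ar_coeff: float = 0.95,
    rec_alpha_boost: float = 3.0,
) -> Recording:
    """Simulate one resting recording (eyes open or closed).

    The frontal theta source is scaled by ``profile.theta_level``; the
    eyes-closed condition enlarges the occipito-parietal alpha source by
    ``rec_alpha_boost`` (alpha dominance with eyes closed).  Deterministic
    given ``seed``.
    """
    if condition not in ("REO", "REC"):
        raise ValueError(f"unknown resting condition: {condition!r}")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    layout = layout or default_layout()
    n = round(duration_s * fs)
    rng = np.random.default_rng(seed)
    data = np.zeros((layout.n_channels, n))

    if profile.theta_level > 0:
        theta = profile.theta_level * _theta_source(rng, n, fs,
                                                    profile.regularity)
        _project(theta, layout, layout.frontal_set, data)

    alpha_amp = profile.alpha_level
    if condition == "REC":
        alpha_amp *= rec_alpha_boost
    op_set = layout.occipito_parietal_set or layout.central_set
    if alpha_amp > 0:
        alpha = alpha_amp * _band_noise(rng, n, fs, 8.0, 13.0)
        _project(alpha, layout, op_set, data)

    if profile.beta_level > 0:
        beta = profile.beta_level * _band_noise(rng, n, fs, 13.0, 30.0)
        _project(beta, layout, layout.central_set, data)

    if profile.noise_scale > 0:
        data += profile.noise_scale * _ar1_noise(
            rng, (layout.n_channels, n), ar_coeff)

    return Recording(data=data, fs=fs, layout=layout, condition=condition)


def _lateral_halves(layout: ChannelLayout) -> tuple[np.ndarray, np.ndarray]:
    """Left/right halves of the central strip by 10-10 naming convention
    (odd digit = left hemisphere, even digit = right)."""
    left, right = [], []
    for name in layout.central_set:
        digits = [c for c in name if c.isdigit()]
        if not digits:
            continue  # midline (z) channels carry no lateralised effect
        (left if int(digits[-1]) % 2 == 1 else right).append(name)
    return layout.indices(tuple(left)), layout.indices(tuple(right))


def generate_mi_session(
    profile: SubjectProfile,
    n_trials_per_class: int = 21,
    fs: float = 160.0,
    layout: ChannelLayout | None = None,
    seed: int = 0,
    fixation_s: float = 2.0,
    task_s: float = 4.0,
    ar_coeff: float = 0.95,
    mu_amp: float | None = None,
    beta_amp: float | None = None,
) -> Recording:
    """Simulate a labelled two-class motor-imagery session.

    Trials of ``fixation_s + task_s`` seconds are concatenated in
    randomised class order.  During the task window, mu (8-13 Hz) and
    beta (13-30 Hz) power over the hemisphere contralateral to the
    imagined hand is suppressed by ``1 - erd_strength``; fixation
    segments carry no class effect.  Annotations mark the task-cue
    sample of each trial with the class label.
    """
    if n_trials_per_class < 1:
        raise ValueError("need at least one trial per class")
    if fs < 60:
        raise ValueError("fs too low to represent the beta band (need >= 60)")
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    # sensorimotor rhythms are weaker than the occipital alpha generator
    mu_amp = 0.35 * profile.alpha_level if mu_amp is None else mu_amp
    beta_amp = 0.35 * profile.beta_level if beta_amp is None else beta_amp

    labels = np.array(["L"] * n_trials_per_class + ["R"] * n_trials_per_class)
    rng.shuffle(labels)

    n_fix = round(fixation_s * fs)
    n_task = round(task_s * fs)
    n_trial = n_fix + n_task
    n_total = n_trial * len(labels)
    left_idx, right_idx = _lateral_halves(layout)
    w_left = _unimodal_weights(len(left_idx))
    w_right = _unimodal_weights(len(right_idx))

    data = np.zeros((layout.n_channels, n_total))
    annotations: list[tuple[int, str]] = []
    att = np.sqrt(1.0 - profile.erd_strength)  # amplitude factor for power x(1-erd)

    for k, label in enumerate(labels):
        start = k * n_trial
        seg = slice(start, start + n_trial)
        trial = np.zeros((layout.n_channels, n_trial))

        # task-window amplitude envelope per hemisphere; contralateral
        # suppression: left-hand imagery ("L") suppresses the right strip
        env_left = np.ones(n_trial)
        env_right = np.ones(n_trial)
        if label == "L":
            env_right[n_fix:] = att
        else:
            env_left[n_fix:] = att

        for idx, w, env in ((left_idx, w_left, env_left),
                            (right_idx, w_right, env_right)):
            if len(idx) == 0:
                continue
            src = (mu_amp * _band_noise(rng, n_trial, fs, 8.0, 13.0)
                   + beta_amp * _band_noise(rng, n_trial, fs, 13.0, 30.0))
            trial[idx] += w[:, None] * (env * src)[None, :]

        if profile.theta_level > 0:
            theta = profile.theta_level * _theta_source(
                rng, n_trial, fs, profile.regularity)
            _project(theta, layout, layout.frontal_set, trial)

        data[:, seg] = trial
        annotations.append((start + n_fix, str(label)))

    if profile.noise_scale > 0:
        data += profile.noise_scale * _ar1_noise(
            rng, (layout.n_channels, n_total), ar_coeff)

    return Recording(data=data, fs=fs, layout=layout, condition="MI",
                     annotations=annotations)


# ---------------------------------------------------------------------------
# persistence: one float32 array + JSON header per recording


def save_recording(recording: Recording, stem: str | "os.PathLike[str]") -> None:
    """Write ``<stem>.npy`` (float32 samples) and ``<stem>.json``
    (rate, condition, channel names, annotations)."""
    import json
    from pathlib import Path

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), recording.data.astype(np.float32))
    header = {
        "fs": recording.fs,
        "condition": recording.condition,
        "channels": list(recording.layout.names),
        "frontal_set": list(recording.layout.frontal_set),
        "central_set": list(recording.layout.central_set),
        "occipito_parietal_set": list(recording.layout.occipito_parietal_set),
        "annotations": [[int(onset), label]
                        for onset, label in recording.annotations],
    }
    stem.with_suffix(".json").write_text(json.dumps(header))


def load_recording(stem: str | "os.PathLike[str]") -> Recording:
    """Read a recording written by :func:`save_recording`."""
    import json
    from pathlib import Path

    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    layout = ChannelLayout(
        names=tuple(header["channels"]),
        frontal_set=tuple(header["frontal_set"]),
        central_set=tuple(header["central_set"]),
        occipito_parietal_set=tuple(header["occipito_parietal_set"]),
    )
    data = np.load(stem.with_suffix(".npy")).astype(float)
    return Recording(data=data, fs=header["fs"], layout=layout,
                     condition=header["condition"],
                     annotations=[(int(o), str(l))
                                  for o, l in header["annotations"]])


# ---------------------------------------------------------------------------
# cohort


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic stream of integer seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32) % (2**31)


def draw_profiles(spec: EffectSpec) -> tuple[list[SubjectProfile],
                                             list[SubjectProfile]]:
    """Draw subject profiles with the planted latent correlation.

    Returns ``(profiles, rec_profiles)``: the second list carries
    independently redrawn theta parameters used for the eyes-closed
    recording, so the planted link is specific to eyes-open.

    The construction is a Gaussian copula: a shared latent factor ``g``
    drives theta level and regularity through the normal CDF; the
    decodability latent is ``rho * g + sqrt(1 - rho^2) * e`` squashed to
    the configured ``erd_range``.  Monotone squashing approximately
    preserves the Pearson correlation and exactly preserves the rank
    correlation's sign and ordering.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC0)))
    n = spec.n_subjects
    g = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z_erd = spec.rho * g + np.sqrt(1.0 - spec.rho**2) * e
    g_rec = rng.standard_normal(n)  # independent REC theta factor

    def squash(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
        return lo + (hi - lo) * stats.norm.cdf(z)

    theta = squash(g, *spec.theta_range)
    reg = squash(g, *spec.regularity_range)
    erd = squash(z_erd, *spec.erd_range)
    theta_rec = squash(g_rec, *spec.theta_range)
    reg_rec = squash(g_rec, *spec.regularity_range)
    alpha = rng.uniform(0.8, 1.4, size=n)
    beta = rng.uniform(0.3, 0.7, size=n)

    profiles, rec_profiles = [], []
    for i in range(n):
        p = SubjectProfile(
            subject_id=i,
            theta_level=float(theta[i]),
            alpha_level=float(alpha[i]),
            beta_level=float(beta[i]),
            regularity=float(reg[i]),
            erd_strength=float(erd[i]),
            noise_scale=1.0,
        )
        profiles.append(p)
        rec_profiles.append(replace(p, theta_level=float(theta_rec[i]),
                                    regularity=float(reg_rec[i])))
    return profiles, rec_profiles


def generate_cohort(
    spec: EffectSpec,
    fs: float = 160.0,
    layout: ChannelLayout | None = None,
    duration_s: float = 60.0,
    n_trials_per_class: int = 21,
    conditions: tuple[str, ...] = ("REO", "REC"),
    with_mi: bool = True,
) -> tuple[list[SubjectProfile],
           dict[int, dict[str, Recording]],
           dict[int, Recording]]:
    """Generate profiles plus REO/REC resting and MI recordings.

    All randomness flows from ``spec.seed``; identical specs produce
    bit-identical cohorts.
    """
    layout = layout or default_layout()
    profiles, rec_profiles = draw_profiles(spec)
    seeds = _child_seeds(spec.seed, 3 * spec.n_subjects)
    resting: dict[int, dict[str, Recording]] = {}
    mi: dict[int, Recording] = {}
    for i, (prof, prof_rec) in enumerate(zip(profiles, rec_profiles)):
        resting[prof.subject_id] = {}
        if "REO" in conditions:
            resting[prof.subject_id]["REO"] = generate_resting_recording(
                prof, "REO", duration_s, fs, layout, seed=int(seeds[3 * i]))
        if "REC" in conditions:
            resting[prof.subject_id]["REC"] = generate_resting_recording(
                prof_rec, "REC", duration_s, fs, layout,
                seed=int(seeds[3 * i + 1]))
        if with_mi:
            mi[prof.subject_id] = generate_mi_session(
                prof, n_trials_per_class, fs, layout,
                seed=int(seeds[3 * i + 2]))
    return profiles, resting, mi
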