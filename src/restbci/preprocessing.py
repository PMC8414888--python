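"""Filtering, segmentation and baseline correction of recordings.

Resting recordings are band-pass filtered (0.1-55 Hz by default) with a
zero-phase windowed-sinc FIR (forward-backward application), then cut
into 30 two-second epochs.  Motor-imagery sessions are cut into one
epoch per trial covering the 4-s task window, with the mean of the
preceding 2-s fixation subtracted per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from restbci.cohort import ChannelLayout, Recording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "bandpass_zero_phase",
    "segment_resting",
    "extract_mi_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    """Windowed-sinc band-pass descriptor.

    ``order`` (number of taps minus one) is derived from
    ``transition_hz`` via the Hamming-window rule order = 3.3 fs / dF
    when not given explicitly.  Forward-backward application doubles the
    stopband attenuation and cancels the phase.
    """

    low_hz: float
    high_hz: float
    transition_hz: float = 1.0
    order: int | None = None
    design: str = "hamming"

    def numtaps(self, fs: float) -> int:
        if self.order is not None:
            n = self.order + 1
        else:
            n = int(np.ceil(3.3 * fs / self.transition_hz)) + 1
        return n + 1 if n % 2 == 0 else n  # odd taps -> type-I linear phase

    def validate(self, fs: float) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("need 0 <= low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError("high_hz must be below Nyquist")


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    numtaps = spec.numtaps(fs)
    if spec.low_hz <= 0:
        return signal.firwin(numtaps, spec.high_hz, window=spec.design, fs=fs)
    return signal.firwin(numtaps, [spec.low_hz, spec.high_hz],
                         window=spec.design, pass_zero=False, fs=fs)


def _filtfilt(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase FIR: odd-reflect padding of up to one filter length,
    then one FFT convolution with the forward-backward combined kernel
    (equivalent to applying the filter forward and reversed)."""
    n = x.shape[-1]
    if n < 3:
        raise ValueError("recording too short to filter")
    padlen = min(len(taps), n - 1)
    left = 2.0 * x[..., :1] - x[..., padlen:0:-1]
    right = 2.0 * x[..., -1:] - x[..., -2:-padlen - 2:-1]
    ext = np.concatenate([left, x, right], axis=-1)
    kernel = np.convolve(taps, taps[::-1])
    shape = (1,) * (x.ndim - 1) + (len(kernel),)
    y = signal.oaconvolve(ext, kernel.reshape(shape), mode="same", axes=-1)
    return y[..., padlen:padlen + n]


def _filtfilt_multi(x: np.ndarray, taps_list: list[np.ndarray]) -> np.ndarray:
    """Zero-phase filtering of ``x`` with several same-length FIR
    filters at once (one shared signal FFT); returns an array with a
    new leading filter axis."""
    lengths = {len(t) for t in taps_list}
    if len(lengths) != 1:
        return np.stack([_filtfilt(x, t) for t in taps_list])
    n = x.shape[-1]
    padlen = min(len(taps_list[0]), n - 1)
    left = 2.0 * x[..., :1] - x[..., padlen:0:-1]
    right = 2.0 * x[..., -1:] - x[..., -2:-padlen - 2:-1]
    ext = np.concatenate([left, x, right], axis=-1)
    kernels = np.stack([np.convolve(t, t[::-1]) for t in taps_list])
    kshape = (len(taps_list),) + (1,) * (x.ndim - 1) + (kernels.shape[-1],)
    # mode="same" crops to in1's shape, so in1 must carry the filter axis
    in1 = np.broadcast_to(ext[None], (len(taps_list),) + ext.shape)
    y = signal.oaconvolve(in1, kernels.reshape(kshape), mode="same", axes=-1)
    return y[..., padlen:padlen + n]


def bandpass_zero_phase(recording: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase band-pass filter; returns a new Recording."""
    taps = design_fir(spec, recording.fs)
    if recording.n_samples < 3:
        raise ValueError("recording too short to filter")
    data = _filtfilt(recording.data, taps)
    return Recording(data=data, fs=recording.fs, layout=recording.layout,
                     condition=recording.condition,
                     annotations=list(recording.annotations))


@dataclass
class EpochSet:
    """Fixed-length windows cut from a recording.

    ``epochs`` is [n_epochs x channels x samples]; ``labels`` is present
    only for motor-imagery epochs.
    """

    epochs: np.ndarray
    fs: float
    layout: ChannelLayout
    condition: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [n_epochs x channels x samples]")
        if (self.labels is None) and self.condition == "MI":
            raise ValueError("MI epochs require labels")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.epochs.shape[0]:
                raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def segment_resting(
    recording: Recording,
    epoch_s: float = 2.0,
    n_epochs: int = 30,
    seed: int = 0,
    random_start: bool = False,
) -> EpochSet:
    """Cut a resting recording into ``n_epochs`` epochs of ``epoch_s`` s.

    Default: the contiguous non-overlapping partition of the first
    ``n_epochs * epoch_s`` seconds, presented in randomised order (a
    60-s recording yields exactly 30 x 2 s).  ``random_start=True``
    instead draws possibly-overlapping random start points.
    Deterministic given ``seed``.
    """
    n_per = round(epoch_s * recording.fs)
    rng = np.random.default_rng(seed)
    if random_start:
        max_start = recording.n_samples - n_per
        if max_start < 0:
            raise ValueError("recording shorter than one epoch")
        starts = rng.integers(0, max_start + 1, size=n_epochs)
    else:
        if n_epochs * n_per > recording.n_samples:
            raise ValueError(
                f"recording too short: need {n_epochs * n_per} samples for "
                f"{n_epochs} non-overlapping epochs, have {recording.n_samples}")
        starts = np.arange(n_epochs) * n_per
        starts = starts[rng.permutation(n_epochs)]
    epochs = np.stack([recording.data[:, s:s + n_per] for s in starts])
    return EpochSet(epochs=epochs, fs=recording.fs, layout=recording.layout,
                    condition=recording.condition)


def extract_mi_epochs(
    session: Recording,
    task_s: float = 4.0,
    fixation_s: float = 2.0,
) -> EpochSet:
    """One baseline-corrected epoch per annotated motor-imagery trial.

    Each epoch covers the ``task_s`` window starting at the annotated
    cue onset; the per-channel mean of the preceding ``fixation_s``
    window is subtracted.
    """
    if not session.annotations:
        raise ValueError("session has no trial annotations")
    n_task = round(task_s * session.fs)
    n_fix = round(fixation_s * session.fs)
    epochs, labels = [], []
    for onset, label in session.annotations:
        if onset - n_fix < 0 or onset + n_task > session.n_samples:
            raise ValueError(f"trial at sample {onset} extends past recording")
        fixation = session.data[:, onset - n_fix:onset]
        task = session.data[:, onset:onset + n_task]
        epochs.append(task - fixation.mean(axis=1, keepdims=True))
        labels.append(label)
    return EpochSet(epochs=np.stack(epochs), fs=session.fs,
                    layout=session.layout, condition="MI",
                    labels=np.array(labels))
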