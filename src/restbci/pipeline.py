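"""End-to-end orchestration: simulate -> preprocess -> featurise ->
decode -> group -> associate, as one reproducible, seeded run.

Every module parameter defaults to the reference analysis settings
(0.1-55 Hz band-pass, 30 x 2-s epochs, sample entropy m=1 r=0.2,
permutation entropy D=3 tau=1, recurrence eps=0.3 with l_min=v_min=2,
nine 4-Hz filter-bank bands with m=2 CSP pairs, 5x5-fold CV, grouping
thresholds 0.594/0.658, screening at p<0.01 and |r|>0.3).  All
randomness flows from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from restbci import cohort as coh
from restbci import entropy as ent
from restbci import rqa as rqa_mod
from restbci.fbcsp import CvScheme, DecodingResult, FilterBank, cross_validate
from restbci.grouping import DEFAULT_THRESHOLDS, assign_groups, to_kappa
from restbci.preprocessing import (EpochSet, FilterSpec, bandpass_zero_phase,
                                   extract_mi_epochs, segment_resting)
from restbci.spectral import BandScheme, spectral_feature_set
from restbci.stats import (aggregate_subject_features, build_association_table,
                           screen_features)

__all__ = [
    "RunConfig",
    "default_study_config",
    "extract_epoch_features",
    "subject_resting_features",
    "run_pipeline",
    "ingest_edf",
]

log = logging.getLogger("restbci")


@dataclass
class RunConfig:
    """One declarative home for every stage's parameters."""

    # cohort
    n_subjects: int = 40
    rho: float = 0.6
    seed: int = 7
    fs: float = 160.0
    duration_s: float = 60.0
    n_trials_per_class: int = 21
    # preprocessing
    filter_low: float = 0.1
    filter_high: float = 55.0
    epoch_s: float = 2.0
    n_epochs: int = 30
    # features
    sampen: ent.SampEnParams = field(default_factory=ent.SampEnParams)
    permen: ent.PermEnParams = field(default_factory=ent.PermEnParams)
    rqa: rqa_mod.RecurrenceParams = field(
        default_factory=rqa_mod.RecurrenceParams)
    bands: BandScheme = field(default_factory=BandScheme)
    # decoding
    bank: FilterBank = field(default_factory=FilterBank)
    n_csp_pairs: int = 2
    qda_shrinkage: float = 0.1
    cv: CvScheme = field(default_factory=CvScheme)
    # grouping + statistics
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    alphas: tuple[float, ...] = (0.05, 0.01)
    p_threshold: float = 0.01
    r_threshold: float = 0.3
    family: str = "per_feature"
    conditions: tuple[str, ...] = ("REO", "REC")
    out_dir: str = "results/run"

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.n_epochs * self.epoch_s > self.duration_s:
            raise ValueError(
                f"n_epochs={self.n_epochs} x epoch_s={self.epoch_s}s exceeds "
                f"recording duration {self.duration_s}s")
        if self.filter_high >= self.fs / 2:
            raise ValueError("filter_high must be below Nyquist")
        if self.n_trials_per_class < self.cv.n_folds:
            raise ValueError("too few trials per class for the CV folds")

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.filter_low, self.filter_high)

    def effect_spec(self) -> coh.EffectSpec:
        return coh.EffectSpec(rho=self.rho, n_subjects=self.n_subjects,
                              seed=self.seed)

    def to_jsonable(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=str))


def default_study_config(**overrides) -> RunConfig:
    """The reference synthetic study: 40 subjects, planted rho = 0.6."""
    cfg = RunConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# feature extraction


def extract_epoch_features(
    epochs: EpochSet,
    subject: int,
    sampen: ent.SampEnParams | None = None,
    permen: ent.PermEnParams | None = None,
    rqa_params: rqa_mod.RecurrenceParams | None = None,
    bands: BandScheme | None = None,
) -> pd.DataFrame:
    """All 17 per-channel features of every epoch, as a tidy table.

    Columns: subject, condition, channel, feature, epoch, value.
    Features: medfreq, shanen, the 10 band-power ratios, sampen, permen,
    det, lam, mrt.
    """
    bands = bands or BandScheme()
    n_ep, n_ch, _ = epochs.epochs.shape
    feature_values: dict[str, np.ndarray] = {}

    spec_names = ["medfreq", "shanen"] + bands.ratio_names
    spec_arr = {name: np.empty((n_ep, n_ch)) for name in spec_names}
    se_arr = np.empty((n_ep, n_ch))
    pe_arr = np.empty((n_ep, n_ch))
    rq_arr = {k: np.empty((n_ep, n_ch)) for k in ("det", "lam", "mrt")}

    for e in range(n_ep):
        x = epochs.epochs[e]  # [channels x samples]
        feats = spectral_feature_set(x, epochs.fs, bands)
        for name in spec_names:
            spec_arr[name][e] = feats[name]
        x32 = x.astype(np.float32)  # pairwise-distance features in single precision
        se_arr[e] = ent.sample_entropy_batch(x32, sampen)
        pe_arr[e] = ent.permutation_entropy_batch(x32, permen)
        rq = rqa_mod.rqa_measures_batch(x32, rqa_params)
        for k in rq_arr:
            rq_arr[k][e] = rq[k]

    feature_values.update(spec_arr)
    feature_values["sampen"] = se_arr
    feature_values["permen"] = pe_arr
    feature_values.update(rq_arr)

    channels = np.asarray(epochs.layout.names)
    frames = []
    for name, arr in feature_values.items():
        frames.append(pd.DataFrame({
            "subject": subject,
            "condition": epochs.condition,
            "channel": np.tile(channels, n_ep),
            "feature": name,
            "epoch": np.repeat(np.arange(n_ep), n_ch),
            "value": arr.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def subject_resting_features(
    recordings: dict[str, coh.Recording],
    subject: int,
    config: RunConfig,
) -> pd.DataFrame:
    """Filter, segment and featurise one subject's resting recordings;
    returns the subject-level (epoch-averaged) aggregate table."""
    spec = config.filter_spec()
    tables = []
    for condition, rec in recordings.items():
        filtered = bandpass_zero_phase(rec, spec)
        epochs = segment_resting(filtered, config.epoch_s, config.n_epochs,
                                 seed=config.seed + subject)
        table = extract_epoch_features(
            epochs, subject, config.sampen, config.permen, config.rqa,
            config.bands)
        tables.append(aggregate_subject_features(table))
    return pd.concat(tables, ignore_index=True)


def decode_subject(mi_recording: coh.Recording, subject: int,
                   config: RunConfig) -> DecodingResult:
    epochs = extract_mi_epochs(mi_recording)
    scheme = CvScheme(n_folds=config.cv.n_folds,
                      n_repeats=config.cv.n_repeats,
                      seed=config.cv.seed + subject)
    return cross_validate(epochs, config.bank, scheme,
                          n_pairs=config.n_csp_pairs,
                          shrinkage=config.qda_shrinkage,
                          subject_id=subject)


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run every stage on a synthetic cohort; returns the in-memory
    tables and (optionally) persists them under ``config.out_dir``.

    Outputs: manifest.csv (ground-truth profiles), features.csv
    (subject-level feature means), decoding.csv (per repeat x fold
    accuracies), performance.csv (max accuracy, kappa, group),
    associations.csv (screened association records), config.json.
    """
    config.validate()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(config.to_jsonable(), indent=2))

    t0 = time.time()
    log.info("simulating cohort: n=%d rho=%.2f seed=%d",
             config.n_subjects, config.rho, config.seed)
    profiles, resting, mi = coh.generate_cohort(
        config.effect_spec(), config.fs, duration_s=config.duration_s,
        n_trials_per_class=config.n_trials_per_class,
        conditions=config.conditions)
    manifest = pd.DataFrame([asdict(p) for p in profiles])

    log.info("extracting resting-state features (%d subjects x %s)",
             len(profiles), "/".join(config.conditions))
    feature_frames, failures = [], []
    for p in profiles:
        try:
            feature_frames.append(subject_resting_features(
                resting[p.subject_id], p.subject_id, config))
        except Exception as err:  # pragma: no cover - defensive per-subject skip
            log.warning("subject %d features failed: %s", p.subject_id, err)
            failures.append((p.subject_id, "features", str(err)))
    features = pd.concat(feature_frames, ignore_index=True)

    log.info("decoding motor-imagery sessions (FBCSP + QDA, %dx%d-fold CV)",
             config.cv.n_repeats, config.cv.n_folds)
    decoding_rows, perf_rows = [], []
    for p in profiles:
        res = decode_subject(mi[p.subject_id], p.subject_id, config)
        for rep in range(res.fold_accuracies.shape[0]):
            for fold in range(res.fold_accuracies.shape[1]):
                decoding_rows.append({
                    "subject": p.subject_id, "decoder": res.decoder,
                    "repeat": rep, "fold": fold,
                    "accuracy": res.fold_accuracies[rep, fold]})
        perf_rows.append({"subject": p.subject_id,
                          "fbcsp": res.mean_accuracy})
    decoding = pd.DataFrame(decoding_rows)

    performance = pd.DataFrame(perf_rows)
    decoder_cols = [c for c in performance.columns if c != "subject"]
    performance["max_accuracy"] = performance[decoder_cols].max(axis=1)
    performance["kappa"] = to_kappa(performance["max_accuracy"].to_numpy())
    performance["group"] = assign_groups(
        performance["max_accuracy"].to_numpy(), config.thresholds)

    log.info("association screening (p<%.3g, |r|>%.2g, %s family)",
             config.p_threshold, config.r_threshold, config.family)
    records = build_association_table(features, performance)
    associations = screen_features(records, config.p_threshold,
                                   config.r_threshold, config.family)

    log.info("pipeline finished in %.1f s (%d significant records)",
             time.time() - t0, int(associations["significant"].sum()))

    result = {"manifest": manifest, "features": features,
              "decoding": decoding, "performance": performance,
              "associations": associations, "failures": failures}
    if write:
        for name in ("manifest", "features", "decoding", "performance",
                     "associations"):
            result[name].to_csv(out / f"{name}.csv", index=False)
    return result


# ---------------------------------------------------------------------------
# optional ingest of real EDF corpora


# run numbers of the public motor-imagery corpus: R01 eyes-open rest,
# R02 eyes-closed rest; imagery runs (left/right fist, fists/feet)
_REST_RUNS = {1: "REO", 2: "REC"}
_IMAGERY_RUNS = (4, 6, 8, 10, 12, 14)


def ingest_edf(
    directory: str | Path,
    layout: coh.ChannelLayout | None = None,
    subject_exclude: tuple[str, ...] = (),
) -> dict[str, dict[str, list[coh.Recording]]]:
    """Read an EDF corpus with the standard run structure.

    Expects ``<directory>/S###/S###R##.edf`` files with T0/T1/T2
    annotations on imagery runs; maps run 1/2 to REO/REC and the six
    imagery runs to MI sessions, drops the eight excluded channels, and
    honours ``subject_exclude`` (subject directory names).  Requires
    :mod:`mne`.
    """
    import mne  # optional dependency, imported lazily

    layout = layout or coh.default_layout()
    directory = Path(directory)
    wanted = {name.upper(): name for name in layout.names}
    out: dict[str, dict[str, list[coh.Recording]]] = {}
    subject_dirs = sorted(d for d in directory.iterdir() if d.is_dir())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {directory}")
    for subj_dir in subject_dirs:
        if subj_dir.name in subject_exclude:
            continue
        sessions: dict[str, list[coh.Recording]] = {
            "REO": [], "REC": [], "MI": []}
        for edf_path in sorted(subj_dir.glob("*.edf")):
            run = int(edf_path.stem[-2:])
            condition = _REST_RUNS.get(run)
            if condition is None and run not in _IMAGERY_RUNS:
                continue
            raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
            rename = {}
            for ch in raw.ch_names:
                key = ch.strip(".").upper()
                if key in wanted:
                    rename[ch] = wanted[key]
            raw.rename_channels(rename)
            missing = set(layout.names) - set(raw.ch_names)
            if missing:
                raise ValueError(
                    f"{edf_path}: montage lacks channels {sorted(missing)}")
            raw.pick(list(layout.names))
            raw.reorder_channels(list(layout.names))
            data = raw.get_data() * 1e6  # volts -> microvolts
            annotations: list[tuple[int, str]] = []
            if condition is None:
                fs = raw.info["sfreq"]
                for onset, desc in zip(raw.annotations.onset,
                                       raw.annotations.description):
                    if desc in ("T1", "T2"):
                        annotations.append(
                            (round(onset * fs), "L" if desc == "T1" else "R"))
                if not annotations:
                    raise ValueError(
                        f"{edf_path}: imagery run has no T1/T2 annotations")
            rec = coh.Recording(data=data, fs=raw.info["sfreq"], layout=layout,
                                condition=condition or "MI",
                                annotations=annotations)
            sessions[condition or "MI"].append(rec)
        out[subj_dir.name] = sessions
    return out
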