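"""Filter-bank CSP + QDA decoding of two-class motor-imagery epochs.

Each baseline-corrected task epoch is band-pass filtered into nine 4-Hz
bands (4-8, 8-12, ..., 36-40 Hz).  Per band, common spatial patterns
solve the generalized eigenproblem

    S_1 W = (S_1 + S_2) W D,

where S_c is the average (trace-normalised) trial covariance of class
c; eigenvalues lie in [0, 1] and the columns of W sorted by descending
eigenvalue are the spatial filters.  The feature vector of a trial is
the log of the normalised variances along the first m and last m
filters of every band (9 x 2m = 36 entries for m = 2, all <= 0), fed to
a quadratic discriminant classifier with covariance shrinkage toward
the diagonal.  Decodability is summarised by 5x5-fold stratified
cross-validation with CSP fitted inside each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.model_selection import RepeatedStratifiedKFold

from restbci.preprocessing import (EpochSet, FilterSpec, design_fir,
                                   _filtfilt_multi)

__all__ = [
    "FilterBank",
    "CspModel",
    "CvScheme",
    "DecodingResult",
    "apply_filter_bank",
    "csp_eigendecomposition",
    "csp_fit",
    "csp_features",
    "ShrinkageQda",
    "cross_validate",
]


def _default_bands() -> tuple[tuple[float, float], ...]:
    return tuple((4.0 + 4 * k, 8.0 + 4 * k) for k in range(9))


@dataclass(frozen=True)
class FilterBank:
    """Nine contiguous 4-Hz bands, 4-40 Hz."""

    bands: tuple[tuple[float, float], ...] = field(default_factory=_default_bands)
    transition_hz: float = 3.0

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("filter bank is empty")


@dataclass
class CspModel:
    """Per-band spatial filters and eigenvalues (descending)."""

    filters: list[np.ndarray]      # per band: [channels x channels]
    eigenvalues: list[np.ndarray]  # per band: [channels], descending
    n_pairs: int = 2

    def selected(self, band: int) -> np.ndarray:
        """First m and last m filter columns of one band."""
        W = self.filters[band]
        m = self.n_pairs
        return np.concatenate([W[:, :m], W[:, -m:]], axis=1)


@dataclass(frozen=True)
class CvScheme:
    n_folds: int = 5
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0


@dataclass
class DecodingResult:
    subject_id: int
    decoder: str
    fold_accuracies: np.ndarray  # [n_repeats x n_folds]

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


def apply_filter_bank(epochs: EpochSet,
                      bank: FilterBank | None = None) -> np.ndarray:
    """Zero-phase band-pass copies of every epoch.

    Returns [n_bands x n_trials x channels x samples].
    """
    bank = bank or FilterBank()
    top = max(high for _, high in bank.bands)
    if epochs.fs / 2 <= top:
        raise ValueError("highest filter-bank band is at or above Nyquist")
    taps = [design_fir(FilterSpec(low, high, transition_hz=bank.transition_hz),
                       epochs.fs)
            for low, high in bank.bands]
    return _filtfilt_multi(epochs.epochs, taps)


def csp_eigendecomposition(S1: np.ndarray, S2: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Solve S1 W = (S1 + S2) W D.

    Returns (W, d) with eigenvalues d in [0, 1] sorted descending and
    filter columns ordered accordingly.  Eigenvalues for the swapped
    class order are 1 - d with the same filters in reversed order.
    """
    d, W = linalg.eigh(S1, S1 + S2)
    order = np.argsort(d)[::-1]
    return W[:, order], d[order]


def _trial_covariances(banded: np.ndarray, normalise: bool) -> np.ndarray:
    """Per-band, per-trial spatial covariances E E^T.

    ``banded`` is [bands x trials x channels x samples]; with
    ``normalise`` each covariance is divided by its trace.
    """
    covs = np.matmul(banded, banded.swapaxes(-1, -2))
    if normalise:
        tr = np.trace(covs, axis1=2, axis2=3)
        tr = np.where(tr > 0, tr, 1.0)
        covs = covs / tr[:, :, None, None]
    return covs


def csp_fit(banded: np.ndarray, labels: np.ndarray,
            n_pairs: int = 2, ridge: float = 1e-6) -> CspModel:
    """Fit per-band CSP filters from banded training epochs.

    Trial covariances are trace-normalised before within-class
    averaging; a ridge term ``ridge * trace/channels * I`` keeps the
    composite covariance full rank.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("CSP requires exactly two classes in the labels")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need at least two trials per class")
    covs = _trial_covariances(banded, normalise=True)
    return _fit_from_covs(covs, labels, n_pairs, ridge)


def csp_features(banded: np.ndarray, model: CspModel) -> np.ndarray:
    """Log-normalised variance features of (possibly many) trials.

    ``banded`` is [bands x trials x channels x samples]; returns
    [trials x bands*2m] with every entry <= 0 (log of a variance
    fraction).  Trials with zero projected variance in a band yield NaN
    entries for that band.
    """
    n_bands, n_trials = banded.shape[:2]
    feats = np.empty((n_trials, n_bands * 2 * model.n_pairs))
    for b in range(n_bands):
        Wbar = model.selected(b)  # [channels x 2m]
        proj = np.einsum("cf,tcs->tfs", Wbar, banded[b])
        var = (proj ** 2).sum(axis=-1)  # [trials x 2m]
        tot = var.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(tot > 0, np.log(var / tot), np.nan)
        feats[:, b * 2 * model.n_pairs:(b + 1) * 2 * model.n_pairs] = v
    return feats


def _features_from_covs(covs: np.ndarray, model: CspModel) -> np.ndarray:
    """Same features computed from precomputed trial covariances
    [bands x trials x channels x channels] (used by cross-validation to
    avoid re-projecting raw epochs in every fold)."""
    n_bands, n_trials = covs.shape[:2]
    feats = np.empty((n_trials, n_bands * 2 * model.n_pairs))
    for b in range(n_bands):
        Wbar = model.selected(b)
        var = np.einsum("cf,tcd,df->tf", Wbar, covs[b], Wbar)
        tot = var.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(tot > 0, np.log(np.maximum(var, 1e-300) / tot), np.nan)
        feats[:, b * 2 * model.n_pairs:(b + 1) * 2 * model.n_pairs] = v
    return feats


class ShrinkageQda:
    """Quadratic discriminant analysis with diagonal shrinkage.

    Class-conditional Gaussians with per-class covariance
    ``(1 - s) * Sigma_c + s * diag(Sigma_c)``; maximum-posterior
    decision with empirical priors.  Shrinkage keeps the 36-feature
    covariance invertible with the ~2 x 17 training trials a fold
    provides.
    """

    def __init__(self, shrinkage: float = 0.1, jitter: float = 1e-9):
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
        self.shrinkage = shrinkage
        self.jitter = jitter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageQda":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.means_, self._chol, self._logdet, self.priors_ = [], [], [], []
        n = len(y)
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise ValueError("need at least two trials per class")
            mu = Xc.mean(axis=0)
            S = np.cov(Xc, rowvar=False, ddof=1)
            S = (1 - self.shrinkage) * S + self.shrinkage * np.diag(np.diag(S))
            S += self.jitter * np.trace(S) / S.shape[0] * np.eye(S.shape[0])
            try:
                L = linalg.cholesky(S, lower=True)
            except linalg.LinAlgError as err:
                raise ValueError(
                    "degenerate class covariance; increase shrinkage") from err
            self.means_.append(mu)
            self._chol.append(L)
            self._logdet.append(2.0 * np.log(np.diag(L)).sum())
            self.priors_.append(len(Xc) / n)
        return self

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k, (mu, L, logdet, prior) in enumerate(
                zip(self.means_, self._chol, self._logdet, self.priors_)):
            z = linalg.solve_triangular(L, (X - mu).T, lower=True)
            maha = (z ** 2).sum(axis=0)
            scores[:, k] = -0.5 * (maha + logdet) + np.log(prior)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]


def cross_validate(
    epochs: EpochSet,
    bank: FilterBank | None = None,
    scheme: CvScheme | None = None,
    n_pairs: int = 2,
    shrinkage: float = 0.1,
    subject_id: int = -1,
    leaky: bool = False,
) -> DecodingResult:
    """Repeated stratified k-fold FBCSP + QDA accuracy.

    CSP filters and the classifier are fitted inside each training fold
    only (``leaky=True`` fits CSP on all trials first — provided solely
    to demonstrate the inflation that leakage causes).  Deterministic
    given ``scheme.seed``; returns the n_repeats x n_folds accuracies.
    """
    bank = bank or FilterBank()
    scheme = scheme or CvScheme()
    labels = np.asarray(epochs.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < scheme.n_folds:
        raise ValueError("too few trials per class for the fold count")

    banded = apply_filter_bank(epochs, bank)
    covs = _trial_covariances(banded, normalise=False)
    covs_norm = _trial_covariances(banded, normalise=True)

    leaky_model = csp_fit(banded, labels, n_pairs=n_pairs) if leaky else None

    splitter = RepeatedStratifiedKFold(
        n_splits=scheme.n_folds, n_repeats=scheme.n_repeats,
        random_state=scheme.seed % (2**31))
    accs = np.empty(scheme.n_folds * scheme.n_repeats)
    for k, (train, test) in enumerate(splitter.split(np.zeros(len(labels)),
                                                     labels)):
        if leaky:
            model = leaky_model
        else:
            model = _fit_from_covs(covs_norm[:, train], labels[train], n_pairs)
        Xtr = _features_from_covs(covs[:, train], model)
        Xte = _features_from_covs(covs[:, test], model)
        clf = ShrinkageQda(shrinkage=shrinkage).fit(Xtr, labels[train])
        accs[k] = float((clf.predict(Xte) == labels[test]).mean())
    return DecodingResult(
        subject_id=subject_id, decoder="fbcsp",
        fold_accuracies=accs.reshape(scheme.n_repeats, scheme.n_folds))


#: named decoder registry; additional decoders (e.g. convolutional
#: networks) plug in here and enter the per-subject maximum accuracy
DECODERS: dict[str, object] = {"fbcsp": cross_validate}


def _fit_from_covs(covs_norm: np.ndarray, labels: np.ndarray,
                   n_pairs: int, ridge: float = 1e-6) -> CspModel:
    """CSP fit from precomputed trace-normalised trial covariances."""
    classes = np.unique(labels)
    n_ch = covs_norm.shape[-1]
    filters, eigenvalues = [], []
    for b in range(covs_norm.shape[0]):
        S1 = covs_norm[b][labels == classes[0]].mean(axis=0)
        S2 = covs_norm[b][labels == classes[1]].mean(axis=0)
        lam = ridge * np.trace(S1 + S2) / n_ch
        eye = lam * np.eye(n_ch)
        W, d = csp_eigendecomposition(S1 + eye, S2 + eye)
        filters.append(W)
        eigenvalues.append(d)
    return CspModel(filters=filters, eigenvalues=eigenvalues, n_pairs=n_pairs)
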