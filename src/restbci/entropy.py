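"""Sample entropy and permutation entropy of single-channel epochs.

Sample entropy: SE(m) = -ln(P_{m+1} / P_m), the negative log conditional
probability that two length-m templates that match within tolerance r
(Chebyshev distance, self-matches excluded) still match at length m+1.
Defaults m = 1, r = 0.2 x SD of the epoch (the standard tolerance
convention; an absolute-tolerance mode is available).

Permutation entropy: Shannon entropy of the ordinal-motif distribution
(embedding dimension D, delay tau) normalised by ln(D!), hence in
[0, 1]: 0 when a single motif occurs, 1 when all D! motifs are
equiprobable.  Defaults D = 3, tau = 1.  Ties are broken by earlier
index ranking lower (stable order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampEnParams",
    "PermEnParams",
    "sample_entropy",
    "sample_entropy_batch",
    "permutation_entropy",
    "permutation_entropy_batch",
    "permutation_entropy_from_counts",
]


@dataclass(frozen=True)
class SampEnParams:
    m: int = 1
    r: float = 0.2
    r_mode: str = "sd"  # "sd": tolerance = r x SD of the series; "absolute"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.r_mode not in ("sd", "absolute"):
            raise ValueError("r_mode must be 'sd' or 'absolute'")


@dataclass(frozen=True)
class PermEnParams:
    D: int = 3
    tau: int = 1

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError("D must be >= 2")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


def sample_entropy(series: np.ndarray,
                   params: SampEnParams | None = None) -> float:
    """Sample entropy of a 1-D series; NaN when no template pair matches
    at either length (the conditional probability is undefined)."""
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if len(x) <= params.m + 1:
        raise ValueError("series too short for the embedding length")
    return float(sample_entropy_batch(x[None, :], params)[0])


def sample_entropy_batch(X: np.ndarray,
                         params: SampEnParams | None = None) -> np.ndarray:
    """Sample entropy of each row of ``X`` [n_series x n_samples].

    Vectorised over series and template pairs: templates of lengths m
    and m+1 both start at i = 0..N-m-1 so the two match counts are over
    the same index set (the convention of the defining work).
    """
    params = params or SampEnParams()
    X = np.atleast_2d(np.asarray(X))
    if not np.issubdtype(X.dtype, np.floating):
        X = X.astype(float)  # single precision passes through unchanged
    n_series, n = X.shape
    m = params.m
    if n <= m + 1:
        raise ValueError("series too short for the embedding length")
    if params.r_mode == "sd":
        tol = params.r * X.std(axis=1)
    else:
        tol = np.full(n_series, params.r)

    # a Chebyshev template match is the AND of scalar matches over the
    # template offsets, so one pairwise comparison matrix serves both
    # template lengths
    D = np.abs(X[:, :, None] - X[:, None, :])  # [s x n x n]
    M = D <= tol[:, None, None]
    n_templ = n - m  # templates start at 0..n_templ-1 for both lengths
    match_m = M[:, :n_templ, :n_templ]
    for k in range(1, m):
        match_m = match_m & M[:, k:k + n_templ, k:k + n_templ]
    match_m1 = match_m & M[:, m:m + n_templ, m:m + n_templ]
    # exclude self-matches (i == j); counts are over ordered pairs i != j,
    # which cancels in the ratio
    count_m = match_m.sum(axis=(1, 2)).astype(float) - n_templ
    count_m1 = match_m1.sum(axis=(1, 2)).astype(float) - n_templ

    out = np.full(n_series, np.nan)
    ok = (count_m > 0) & (count_m1 > 0)
    out[ok] = -np.log(count_m1[ok] / count_m[ok])
    return out


def _motif_codes(X: np.ndarray, D: int, tau: int) -> np.ndarray:
    """Ordinal pattern code of each window, rows of ``X``.

    Windows are x[j], x[j+tau], ..., x[j+(D-1)tau]; the code is the
    permutation that sorts the window ascending (stable, so ties rank by
    earlier index), encoded as an integer in [0, D!).
    """
    n = X.shape[-1]
    n_win = n - (D - 1) * tau
    if n_win < 1:
        raise ValueError("series shorter than one embedding window")
    idx = np.arange(n_win)[:, None] + tau * np.arange(D)[None, :]
    windows = X[..., idx]  # [... x n_win x D]
    order = np.argsort(windows, axis=-1, kind="stable")
    # encode permutation via factorial-base digits (Lehmer-like but a
    # simple positional mix suffices for a bijection on permutations)
    codes = np.zeros(order.shape[:-1], dtype=np.int64)
    for k in range(D):
        codes = codes * D + order[..., k]
    return codes


def permutation_entropy(series: np.ndarray,
                        params: PermEnParams | None = None) -> float:
    """Normalised permutation entropy of a 1-D series, in [0, 1]."""
    params = params or PermEnParams()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    return float(permutation_entropy_batch(x[None, :], params)[0])


def permutation_entropy_batch(X: np.ndarray,
                              params: PermEnParams | None = None) -> np.ndarray:
    """Normalised permutation entropy of each row of ``X``."""
    params = params or PermEnParams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    codes = _motif_codes(X, params.D, params.tau)
    n_series, n_win = codes.shape
    out = np.empty(n_series)
    log_dfact = math.log(math.factorial(params.D))
    for s in range(n_series):
        counts = np.bincount(codes[s])
        out[s] = permutation_entropy_from_counts(
            counts[counts > 0], params.D, _log_dfact=log_dfact)
    return out


def permutation_entropy_from_counts(counts: np.ndarray, D: int,
                                    _log_dfact: float | None = None) -> float:
    """Normalised permutation entropy from a motif frequency table.

    ``counts`` are the (nonnegative) occurrence counts of motifs; the
    Shannon entropy of the induced probabilities is divided by ln(D!).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no motifs observed")
    if counts.size > math.factorial(D):
        raise ValueError("more motifs than D! permutations")
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum()) + 0.0  # normalise IEEE -0.0
    log_dfact = _log_dfact if _log_dfact is not None else math.log(
        math.factorial(D))
    return h / log_dfact
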