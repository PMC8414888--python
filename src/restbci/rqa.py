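"""Recurrence plots and the DET / LAM / MRT recurrence measures.

A recurrence plot marks the sample pairs (i, j) of a (z-normalised,
optionally time-delay embedded) series whose states lie within a
threshold eps of each other under the maximum norm:
R[i, j] = Theta(eps - ||x_i - x_j||), with Theta(0) = 1 (distances equal
to eps count as recurrent).

Measures (minimal line lengths l_min = v_min = 2 by default):

* DET (determinism): fraction of recurrence points on diagonal lines of
  length >= l_min; 1 for a periodic signal, toward 0 for a chaotic one.
* LAM (laminarity): same with vertical lines, reflecting laminar
  (slowly changing) states.
* MRT (mean recurrence time): mean length of the white vertical gaps;
  long for unpredictable signals, missing (NaN) when the plot is
  recurrence-saturated and has no white gaps.

Defaults: eps = 0.3 on the z-normalised series, no embedding
(emb_dim = 1, the recurrence relation applied directly to samples),
line of identity included.  Runs touching the matrix border are counted
at their observed length.

Line counting is vectorised: the matrix (or a whole batch of matrices)
is sheared so diagonals become columns, columns are flattened with
separator rows, and run lengths fall out of one pass of ``np.diff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecurrenceParams",
    "RecurrenceMatrix",
    "LineHistograms",
    "ZeroVarianceError",
    "recurrence_matrix",
    "determinism",
    "laminarity",
    "mean_recurrence_time",
    "line_histograms",
    "rqa_measures",
    "rqa_measures_batch",
]


class ZeroVarianceError(ValueError):
    """The series is constant; z-normalisation is undefined."""


@dataclass(frozen=True)
class RecurrenceParams:
    eps: float = 0.3
    emb_dim: int = 1
    emb_tau: int = 1
    include_loi: bool = True
    l_min: int = 2
    v_min: int = 2
    znorm: bool = True

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.emb_dim < 1 or self.emb_tau < 1:
            raise ValueError("embedding parameters must be >= 1")
        if self.l_min < 2 or self.v_min < 2:
            raise ValueError("minimal line lengths must be >= 2")


@dataclass
class RecurrenceMatrix:
    """Binary recurrence matrix (symmetric, unit main diagonal)."""

    R: np.ndarray  # [N_eff x N_eff] bool
    params: RecurrenceParams

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=bool)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")


@dataclass
class LineHistograms:
    """Counts of diagonal (P_l), vertical (P_v) and white-vertical (P_w)
    line lengths; index = length, entry = number of maximal runs."""

    P_l: np.ndarray
    P_v: np.ndarray
    P_w: np.ndarray


def _embed(x: np.ndarray, dim: int, tau: int) -> np.ndarray:
    """Time-delay embedding of rows of ``x``: [... x N_eff x dim]."""
    n = x.shape[-1]
    n_eff = n - (dim - 1) * tau
    if n_eff < 1:
        raise ValueError("series too short for the embedding")
    idx = np.arange(n_eff)[:, None] + tau * np.arange(dim)[None, :]
    return x[..., idx]


def _recurrence_batch(X: np.ndarray, params: RecurrenceParams) -> np.ndarray:
    """Recurrence matrices of each (already normalised) row of ``X``."""
    emb = _embed(X, params.emb_dim, params.emb_tau)  # [B x N_eff x dim]
    dist = np.abs(emb[:, :, None, :, ] - emb[:, None, :, :]).max(axis=-1)
    R = dist <= params.eps
    if not params.include_loi:
        n_eff = R.shape[-1]
        R[:, np.arange(n_eff), np.arange(n_eff)] = False
    return R


def recurrence_matrix(series: np.ndarray,
                      params: RecurrenceParams | None = None
                      ) -> RecurrenceMatrix:
    """Recurrence plot of a 1-D series.

    The series is z-normalised (mean 0, SD 1) before thresholding so the
    fixed eps is commensurate across subjects; raises
    :class:`ZeroVarianceError` for a constant series.
    """
    params = params or RecurrenceParams()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if len(x) < params.emb_dim:
        raise ValueError("series shorter than the embedding dimension")
    if params.znorm:
        sd = x.std()
        if sd == 0:
            raise ZeroVarianceError("constant series: z-normalisation undefined")
        x = (x - x.mean()) / sd
    R = _recurrence_batch(x[None, :], params)[0]
    return RecurrenceMatrix(R=R, params=params)


# ---------------------------------------------------------------------------
# vectorised run counting


def _runs(flat: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """(matrix ids, lengths) of maximal runs of True in a flat boolean
    array whose blocks of ``stride`` elements belong to one matrix.
    Blocks must already be zero-separated so runs never cross."""
    f = flat.astype(np.int8)
    d = np.diff(np.concatenate((np.zeros(1, np.int8), f, np.zeros(1, np.int8))))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts // stride, ends - starts


def _vertical_run_stream(R: np.ndarray, white: bool) -> tuple[np.ndarray, np.ndarray]:
    """Runs along columns of each matrix in batch ``R`` [B x N x N]."""
    B, n, _ = R.shape
    target = ~R if white else R
    # separator row terminates every column; column-major flatten per matrix
    padded = np.concatenate(
        (target, np.zeros((B, 1, n), dtype=bool)), axis=1)
    flat = padded.transpose(0, 2, 1).reshape(-1)
    return _runs(flat, n * (n + 1))


def _diagonal_run_stream(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Runs along the diagonals of each matrix in batch ``R``."""
    B, n, _ = R.shape
    # shear: flip left-right, pad rows to width 2n, re-cut to width 2n-1;
    # each row then shifts one step, so columns are the diagonals of R
    flipped = R[:, :, ::-1]
    padded = np.concatenate((flipped, np.zeros((B, n, n), dtype=bool)), axis=2)
    sheared = padded.reshape(B, -1)[:, : n * (2 * n - 1)].reshape(B, n, 2 * n - 1)
    with_sep = np.concatenate(
        (sheared, np.zeros((B, 1, 2 * n - 1), dtype=bool)), axis=1)
    flat = with_sep.transpose(0, 2, 1).reshape(-1)
    return _runs(flat, (2 * n - 1) * (n + 1))


def _measures_from_batch(R: np.ndarray, params: RecurrenceParams
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(DET, LAM, MRT) arrays for a batch of recurrence matrices.

    With the default minimal line length 2, "points on lines of length
    >= 2" is just "recurrent points that are not isolated along the
    line direction", and the white-run mean is white cells divided by
    white-run starts — all shifted boolean masks, no run streaming.
    """
    if params.l_min == 2 and params.v_min == 2:
        return _measures_min2(R)
    return _measures_general(R, params)


def _measures_min2(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    total = R.sum(axis=(1, 2)).astype(float)
    n = R.shape[-1]

    # diagonal singletons: no predecessor at (i-1, j-1), no successor at
    # (i+1, j+1)
    succ = np.zeros_like(R)
    succ[:, :-1, :-1] = R[:, 1:, 1:]
    pred = np.zeros_like(R)
    pred[:, 1:, 1:] = R[:, :-1, :-1]
    diag_single = (R & ~succ & ~pred).sum(axis=(1, 2))
    det_num = total - diag_single

    # vertical singletons
    succ[:] = False
    succ[:, :-1, :] = R[:, 1:, :]
    pred[:] = False
    pred[:, 1:, :] = R[:, :-1, :]
    vert_single = (R & ~succ & ~pred).sum(axis=(1, 2))
    lam_num = total - vert_single

    # white vertical runs: cell count / maximal-run count (runs start at
    # the top border or below a recurrent cell)
    W = ~R
    white_total = (n * n - total)
    w_starts = (W[:, 0, :].sum(axis=1)
                + (W[:, 1:, :] & R[:, :-1, :]).sum(axis=(1, 2))).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        det = np.where(total > 0, det_num / total, np.nan)
        lam = np.where(total > 0, lam_num / total, np.nan)
        mrt = np.where(w_starts > 0, white_total / w_starts, np.nan)
    return det, lam, mrt


def _measures_general(R: np.ndarray, params: RecurrenceParams
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B = R.shape[0]
    total = R.sum(axis=(1, 2)).astype(float)

    ids_d, len_d = _diagonal_run_stream(R)
    keep = len_d >= params.l_min
    det_num = np.bincount(ids_d[keep], weights=len_d[keep], minlength=B)

    ids_v, len_v = _vertical_run_stream(R, white=False)
    keep = len_v >= params.v_min
    lam_num = np.bincount(ids_v[keep], weights=len_v[keep], minlength=B)

    ids_w, len_w = _vertical_run_stream(R, white=True)
    w_sum = np.bincount(ids_w, weights=len_w, minlength=B)
    w_cnt = np.bincount(ids_w, minlength=B).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        det = np.where(total > 0, det_num / total, np.nan)
        lam = np.where(total > 0, lam_num / total, np.nan)
        mrt = np.where(w_cnt > 0, w_sum / w_cnt, np.nan)
    return det, lam, mrt


# ---------------------------------------------------------------------------
# public measures


def determinism(rp: RecurrenceMatrix) -> float:
    """Fraction of recurrence points on diagonal lines of length >= l_min."""
    det, _, _ = _measures_from_batch(rp.R[None], rp.params)
    return float(det[0])


def laminarity(rp: RecurrenceMatrix) -> float:
    """Fraction of recurrence points on vertical lines of length >= v_min."""
    _, lam, _ = _measures_from_batch(rp.R[None], rp.params)
    return float(lam[0])


def mean_recurrence_time(rp: RecurrenceMatrix) -> float:
    """Mean length of white vertical gaps; NaN if the plot has none."""
    _, _, mrt = _measures_from_batch(rp.R[None], rp.params)
    return float(mrt[0])


def line_histograms(rp: RecurrenceMatrix) -> LineHistograms:
    """Full length histograms of diagonal, vertical and white lines."""
    R = rp.R[None]
    _, len_d = _diagonal_run_stream(R)
    _, len_v = _vertical_run_stream(R, white=False)
    _, len_w = _vertical_run_stream(R, white=True)
    n = rp.R.shape[0]
    return LineHistograms(
        P_l=np.bincount(len_d, minlength=n + 1),
        P_v=np.bincount(len_v, minlength=n + 1),
        P_w=np.bincount(len_w, minlength=n + 1),
    )


def write_rp_pgm(rp: RecurrenceMatrix, path: str) -> None:
    """Dump a recurrence plot as a plain-text portable graymap (P2),
    black = recurrent, for quick visual inspection."""
    R = rp.R
    n = R.shape[0]
    lines = [f"P2\n{n} {n}\n1"]
    for row in ~R:  # PGM: 0 = black; recurrent points drawn black
        lines.append(" ".join("1" if white else "0" for white in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def rqa_measures(series: np.ndarray,
                 params: RecurrenceParams | None = None
                 ) -> dict[str, float]:
    """DET, LAM and MRT of one series; all NaN for a constant series."""
    params = params or RecurrenceParams()
    try:
        rp = recurrence_matrix(series, params)
    except ZeroVarianceError:
        return {"det": np.nan, "lam": np.nan, "mrt": np.nan}
    det, lam, mrt = _measures_from_batch(rp.R[None], params)
    return {"det": float(det[0]), "lam": float(lam[0]), "mrt": float(mrt[0])}


def rqa_measures_batch(X: np.ndarray,
                       params: RecurrenceParams | None = None
                       ) -> dict[str, np.ndarray]:
    """DET, LAM and MRT for each row of ``X`` [n_series x n_samples].

    Constant rows yield NaN in all three measures.  One shot of batched
    boolean algebra; identical results to the per-series functions.
    """
    params = params or RecurrenceParams()
    X = np.atleast_2d(np.asarray(X))
    if not np.issubdtype(X.dtype, np.floating):
        X = X.astype(float)  # single precision passes through unchanged
    sd = X.std(axis=1)
    ok = sd > 0
    out = {k: np.full(X.shape[0], np.nan) for k in ("det", "lam", "mrt")}
    if not ok.any():
        return out
    Xn = X[ok]
    if params.znorm:
        Xn = (Xn - Xn.mean(axis=1, keepdims=True)) / sd[ok, None]
    R = _recurrence_batch(Xn, params)
    det, lam, mrt = _measures_from_batch(R, params)
    out["det"][ok] = det
    out["lam"][ok] = lam
    out["mrt"][ok] = mrt
    return out
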