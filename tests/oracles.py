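"""Independent brute-force reference implementations.

Deliberately naive (double loops, explicit run scanning) and kept free
of any code from the package under test; used to pin down the entropy
and recurrence measures exactly.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def brute_sample_entropy(x, m=1, r=0.2, r_mode="sd"):
    x = np.asarray(x, dtype=float)
    n = len(x)
    tol = r * x.std() if r_mode == "sd" else r
    n_templ = n - m
    count_m = count_m1 = 0
    for i in range(n_templ):
        for j in range(n_templ):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                count_m += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= tol:
                count_m1 += 1
    if count_m == 0 or count_m1 == 0:
        return float("nan")
    return -math.log(count_m1 / count_m)


def brute_permutation_entropy(x, D=3, tau=1):
    x = np.asarray(x, dtype=float)
    n_windows = len(x) - (D - 1) * tau
    motifs = Counter()
    for j in range(n_windows):
        window = x[j:j + (D - 1) * tau + 1:tau]
        motifs[tuple(np.argsort(window, kind="stable"))] += 1
    total = sum(motifs.values())
    h = -sum(c / total * math.log(c / total) for c in motifs.values())
    return h / math.log(math.factorial(D))


def _run_lengths(cells, value):
    runs, current = [], 0
    for cell in cells:
        if bool(cell) == value:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def brute_rqa_measures(R, l_min=2, v_min=2):
    """DET, LAM, MRT by explicit run scanning of a binary matrix."""
    R = np.asarray(R, dtype=bool)
    n = R.shape[0]
    total = int(R.sum())
    det_num = 0
    for offset in range(-(n - 1), n):
        det_num += sum(l for l in _run_lengths(np.diagonal(R, offset), True)
                       if l >= l_min)
    lam_num = 0
    white_runs = []
    for j in range(n):
        lam_num += sum(l for l in _run_lengths(R[:, j], True) if l >= v_min)
        white_runs.extend(_run_lengths(R[:, j], False))
    det = det_num / total if total else float("nan")
    lam = lam_num / total if total else float("nan")
    mrt = float(np.mean(white_runs)) if white_runs else float("nan")
    return det, lam, mrt


def brute_recurrence_matrix(x, eps=0.3, znorm=True):
    x = np.asarray(x, dtype=float)
    if znorm:
        x = (x - x.mean()) / x.std()
    n = len(x)
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            R[i, j] = abs(x[i] - x[j]) <= eps
    return R


def random_recurrence_like(rng, n, density=0.3):
    """Random symmetric binary matrix with a unit diagonal."""
    R = rng.random((n, n)) < density
    R = R | R.T
    np.fill_diagonal(R, True)
    return R
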