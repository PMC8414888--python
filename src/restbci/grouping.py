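"""Chance-level confidence bounds, performance groups and kappa.

For N subjects with mean accuracy X-bar, the adjusted proportion

    p~ = (N X-bar + 2) / (N + 4)

gives the (Agresti-Coull style) confidence interval

    p~ +/- sqrt(p~ (1 - p~) / (N + 4)) * z_{1 - alpha/2}.

With N = 104 and X-bar at the two-class chance level 0.5, the alpha =
0.05 upper bound is 0.594.  Subjects are split into low / intermediate /
high performance groups by two accuracy thresholds (the reference
values 0.594 and 0.658 by default; boundary values go to the higher
group), and accuracies are rescaled to Cohen's kappa,
kappa = (p_a - p_c) / (1 - p_c), which is 0 at chance and 1 at perfect
classification.

Note: evaluating the bound formula at alpha = 0.01 gives 0.624, not the
0.658 used as the reference high-performance threshold; the formula
value is what :func:`group_thresholds` reports, and the reference pair
remains available as the default override for grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupBounds",
    "PerformanceRecord",
    "group_thresholds",
    "assign_groups",
    "to_kappa",
    "DEFAULT_THRESHOLDS",
]

GROUPS = ("low", "intermediate", "high")
#: reference accuracy thresholds separating low/intermediate/high
DEFAULT_THRESHOLDS = (0.594, 0.658)


@dataclass(frozen=True)
class GroupBounds:
    """Upper/lower confidence bounds around chance per alpha level."""

    n_subjects: int
    xbar: float
    p_tilde: float
    bounds: dict[float, tuple[float, float]]  # alpha -> (lower, upper)

    def upper(self, alpha: float) -> float:
        return self.bounds[alpha][1]


@dataclass
class PerformanceRecord:
    subject_id: int
    accuracies: dict[str, float]  # decoder name -> mean accuracy
    max_accuracy: float
    group: str
    kappa: float


def group_thresholds(
    n_subjects: int,
    xbar: float = 0.5,
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> GroupBounds:
    """Confidence bounds on chance-level accuracy (two-sided normal
    quantile).  ``xbar`` defaults to the two-class chance level."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 < xbar < 1.0:
        raise ValueError("xbar must be in (0, 1)")
    p_tilde = (n_subjects * xbar + 2.0) / (n_subjects + 4.0)
    half_widths = {}
    for alpha in alphas:
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        w = np.sqrt(p_tilde * (1.0 - p_tilde) / (n_subjects + 4.0)) * z
        half_widths[alpha] = (p_tilde - w, p_tilde + w)
    return GroupBounds(n_subjects=n_subjects, xbar=xbar, p_tilde=p_tilde,
                       bounds=half_widths)


def assign_groups(
    accuracies: np.ndarray,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Three-way split of accuracies by two thresholds.

    low < t1 <= intermediate < t2 <= high (boundary values assigned to
    the higher group).
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must be increasing")
    acc = np.asarray(accuracies, dtype=float)
    out = np.where(acc >= t2, "high",
                   np.where(acc >= t1, "intermediate", "low"))
    return out.astype(object)


def to_kappa(accuracy: float | np.ndarray, chance: float = 0.5):
    """Cohen's kappa from accuracy: (p_a - p_c) / (1 - p_c).

    May be negative for below-chance accuracy.
    """
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must be in (0, 1)")
    kappa = (np.asarray(accuracy, dtype=float) - chance) / (1.0 - chance)
    return float(kappa) if kappa.ndim == 0 else kappa
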