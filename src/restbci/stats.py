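"""Screening resting-state features against BCI performance.

Per (condition, feature, channel): subject-level values are the mean of
the feature over epochs; a Kruskal-Wallis omnibus test across the three
performance groups gates two Welch post hoc contrasts ("others vs low"
and "high vs others"), and an ordinary least-squares regression of
kappa on the feature supplies the slope and Pearson r.  A record is
significant iff the Bonferroni-adjusted omnibus p is below 0.01 AND
|r| > 0.3.  The Bonferroni family defaults to the channels of one
(condition, feature) pair; a stricter global family (all channels x
features of a condition) is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_subject_features",
    "kruskal_wallis",
    "welch_contrasts",
    "linear_association",
    "screen_features",
    "build_association_table",
]


def aggregate_subject_features(feature_epochs: pd.DataFrame) -> pd.DataFrame:
    """Epoch-level tidy table -> subject-level means.

    Expects columns ``subject, condition, channel, feature, value`` with
    one row per epoch; returns one row per
    (subject, condition, channel, feature) with ``mean``, ``sd`` and
    ``n_epochs`` (missing epoch values are dropped pairwise and the
    surviving count recorded).
    """
    required = {"subject", "condition", "channel", "feature", "value"}
    missing = required - set(feature_epochs.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    grouped = feature_epochs.groupby(
        ["subject", "condition", "channel", "feature"], sort=False)["value"]
    out = grouped.agg(mean="mean", sd="std", n_epochs="count").reset_index()
    return out


def kruskal_wallis(values: np.ndarray, groups: np.ndarray
                   ) -> tuple[float, float]:
    """Rank-based H statistic (tie-corrected) and chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if all(np.all(s == samples[0][0]) for s in samples):
        return 0.0, 1.0  # all observations identical: no rank variation
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def welch_contrasts(values: np.ndarray, groups: np.ndarray
                    ) -> dict[str, tuple[float, float]]:
    """Welch t and Welch-Satterthwaite dof for the two post hoc
    contrasts: intermediate+high vs low, and high vs low+intermediate.

    Sign convention: the (pooled) better-performing side minus the
    comparison side, so a feature that increases with performance gets
    positive t in both contrasts.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    low = values[groups == "low"]
    high = values[groups == "high"]
    others_vs_low = values[groups != "low"]
    others_vs_high = values[groups != "high"]
    out = {}
    for name, a, b in (("others_vs_low", others_vs_low, low),
                       ("high_vs_others", high, others_vs_high)):
        if len(a) < 2 or len(b) < 2:
            out[name] = (np.nan, np.nan)
            continue
        res = sps.ttest_ind(a, b, equal_var=False)
        out[name] = (float(res.statistic), float(res.df))
    return out


def linear_association(feature_values: np.ndarray, kappas: np.ndarray
                       ) -> tuple[float, float]:
    """OLS slope of kappa on the feature, and Pearson r."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(kappas, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: association undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue)


def build_association_table(
    subject_features: pd.DataFrame,
    performance: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(condition, feature, channel) association records.

    ``subject_features``: output of :func:`aggregate_subject_features`.
    ``performance``: one row per subject with columns
    ``subject, kappa, group``.  Subjects with missing feature values are
    dropped pairwise per record; the surviving count is logged in
    ``n_subjects``.
    """
    perf = performance.set_index("subject")
    records = []
    for (cond, feat, chan), grp in subject_features.groupby(
            ["condition", "feature", "channel"], sort=False):
        merged = grp.set_index("subject").join(perf, how="inner")
        merged = merged.dropna(subset=["mean", "kappa"])
        n = len(merged)
        rec = {"condition": cond, "feature": feat, "channel": chan,
               "n_subjects": n, "slope": np.nan, "r": np.nan,
               "t_others_vs_low": np.nan, "dof_others_vs_low": np.nan,
               "t_high_vs_others": np.nan, "dof_high_vs_others": np.nan,
               "kw_p": np.nan}
        if n >= 3 and merged["mean"].std() > 0 and merged["kappa"].std() > 0:
            rec["slope"], rec["r"] = linear_association(
                merged["mean"].to_numpy(), merged["kappa"].to_numpy())
            groups = merged["group"].to_numpy()
            if len(np.unique(groups)) >= 2:
                _, rec["kw_p"] = kruskal_wallis(merged["mean"].to_numpy(),
                                                groups)
                contrasts = welch_contrasts(merged["mean"].to_numpy(), groups)
                rec["t_others_vs_low"], rec["dof_others_vs_low"] = (
                    contrasts["others_vs_low"])
                rec["t_high_vs_others"], rec["dof_high_vs_others"] = (
                    contrasts["high_vs_others"])
        records.append(rec)
    return pd.DataFrame.from_records(records)


def screen_features(
    records: pd.DataFrame,
    p_threshold: float = 0.01,
    r_threshold: float = 0.3,
    family: str = "per_feature",
) -> pd.DataFrame:
    """Bonferroni adjustment and the conjunction significance rule.

    ``family='per_feature'`` corrects across the channels of each
    (condition, feature) pair; ``family='global'`` corrects across all
    records of a condition.  Adds ``p_adjusted`` and ``significant``
    columns (significant iff p_adjusted < p_threshold and |r| >
    r_threshold); never decreases a p-value.
    """
    if family not in ("per_feature", "global"):
        raise ValueError("family must be 'per_feature' or 'global'")
    out = records.copy()
    if family == "per_feature":
        sizes = out.groupby(["condition", "feature"])["channel"].transform(
            "count")
    else:
        sizes = out.groupby("condition")["channel"].transform("count")
    out["p_adjusted"] = np.minimum(out["kw_p"] * sizes, 1.0)
    out["significant"] = ((out["p_adjusted"] < p_threshold)
                          & (out["r"].abs() > r_threshold)).fillna(False)
    return out
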