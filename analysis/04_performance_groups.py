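"""Assign the three BCI-performance groups and kappa scores.

Reads results/decoding_summary.csv, takes each subject's maximum
accuracy over decoders, converts it to Cohen's kappa, and splits the
cohort at the reference thresholds (0.594 / 0.658).  Also prints the
chance-level confidence bounds the formula gives for this cohort size.
"""

import json

import pandas as pd

from common import RESULTS, study_config
from restbci.grouping import assign_groups, group_thresholds, to_kappa

cfg = study_config()
summary = pd.read_csv(RESULTS / "decoding_summary.csv")
decoders = [c for c in summary.columns if c != "subject"]

summary["max_accuracy"] = summary[decoders].max(axis=1)
summary["kappa"] = to_kappa(summary["max_accuracy"].to_numpy())
summary["group"] = assign_groups(summary["max_accuracy"].to_numpy(),
                                 cfg.thresholds)
summary.to_csv(RESULTS / "performance.csv", index=False)

bounds = group_thresholds(len(summary), 0.5, cfg.alphas)
print(f"chance-level bounds for N={len(summary)} at chance 0.5:")
for alpha, (lo, hi) in bounds.bounds.items():
    print(f"  alpha={alpha}: upper bound {hi:.3f}")
print(f"grouping thresholds used: {cfg.thresholds} "
      f"(reference values for the 104-subject setting)")
counts = summary["group"].value_counts().to_dict()
print(f"group sizes: {counts}")
(RESULTS / "grouping.json").write_text(json.dumps({
    "n_subjects": len(summary), "thresholds": list(cfg.thresholds),
    "alphas": list(cfg.alphas), "group_sizes": counts}, indent=2))
print(f"wrote {RESULTS / 'performance.csv'}")
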