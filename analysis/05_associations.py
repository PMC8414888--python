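"""Screen resting-state features against subsequent BCI performance.

Reads results/features.csv and results/performance.csv, builds the full
association table (regression slope and r, Welch post hoc contrasts,
Kruskal-Wallis omnibus p, Bonferroni adjustment, conjunction screen at
p < 0.01 and |r| > 0.3), writes results/associations.csv, and prints
the strongest frontal-channel association per headline feature.
"""

import pandas as pd

from common import RESULTS, study_config
from restbci.stats import build_association_table, screen_features

FRONTAL = ("Fp1", "Fpz", "Fp2", "AF3", "AFz", "AF4", "F7", "F5", "F3", "F1",
           "Fz", "F2", "F4", "F6", "F8")

cfg = study_config()
features = pd.read_csv(RESULTS / "features.csv")
performance = pd.read_csv(RESULTS / "performance.csv")

records = build_association_table(features, performance)
associations = screen_features(records, cfg.p_threshold, cfg.r_threshold,
                               cfg.family)
associations.to_csv(RESULTS / "associations.csv", index=False)

n_sig = int(associations["significant"].sum())
print(f"{len(associations)} association records, {n_sig} pass the "
      f"conjunction screen (Bonferroni p<{cfg.p_threshold}, "
      f"|r|>{cfg.r_threshold})")
print("strongest frontal eyes-open association per headline feature:")
reo = associations[(associations["condition"] == "REO")
                   & (associations["channel"].isin(FRONTAL))]
for feature in ("theta/hbeta", "det", "lam", "mrt", "shanen"):
    sub = reo[reo["feature"] == feature]
    best = sub.loc[sub["r"].abs().idxmax()]
    print(f"  {feature:12s} {best['channel']:>4s}  r={best['r']:+.2f}  "
          f"slope={best['slope']:+.3g}  kw_p={best['kw_p']:.2e}  "
          f"p_adj={best['p_adjusted']:.3f}")
rec = associations[associations["condition"] == "REC"]
print(f"eyes-closed records passing the screen: "
      f"{int(rec['significant'].sum())} of {len(rec)}")
print(f"wrote {RESULTS / 'associations.csv'}")
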