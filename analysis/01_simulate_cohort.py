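"""Draw the synthetic cohort and record its ground truth.

Writes results/manifest.csv (one row per subject: theta level,
regularity, decodability, noise scale) and prints how strongly the
planted latent correlation shows up in the realised draw.
"""

import numpy as np
import pandas as pd
from dataclasses import asdict

from common import RESULTS, study_config
from restbci.cohort import draw_profiles

cfg = study_config()
profiles, rec_profiles = draw_profiles(cfg.effect_spec())

manifest = pd.DataFrame([asdict(p) for p in profiles])
manifest["theta_level_rec"] = [p.theta_level for p in rec_profiles]
RESULTS.mkdir(exist_ok=True)
manifest.to_csv(RESULTS / "manifest.csv", index=False)

theta = manifest["theta_level"]
erd = manifest["erd_strength"]
print(f"cohort: n={cfg.n_subjects}, planted rho={cfg.rho}, seed={cfg.seed}")
print(f"realised corr(theta_level, erd_strength) = "
      f"{np.corrcoef(theta, erd)[0, 1]:+.3f}")
print(f"realised corr(REC theta_level, erd_strength) = "
      f"{np.corrcoef(manifest['theta_level_rec'], erd)[0, 1]:+.3f} "
      f"(decoupled by construction)")
print(f"wrote {RESULTS / 'manifest.csv'}")
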