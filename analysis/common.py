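"""Shared configuration for the numbered analysis scripts.

One 40-subject synthetic cohort with a planted latent correlation of
0.6 between frontal-theta character (level + regularity) and
motor-imagery decodability; all scripts regenerate data
deterministically from this config, so they can run independently.
"""

from pathlib import Path

from restbci.pipeline import RunConfig, default_study_config

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config() -> RunConfig:
    return default_study_config(n_subjects=40, rho=0.6, seed=7,
                                out_dir=str(RESULTS / "study"))
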