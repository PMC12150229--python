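"""Bootstrapped head-to-head comparison of tract contributions.

Cluster-bootstraps the marginal delta R^2 that each tract's FW adds to a
covariate-only model of memory decline, then ranks tract types; with the
generated effect confined to limbic white matter, limbic tracts should
rank first.
"""

import pandas as pd

from common import study_config
from fwtrace.pipeline import run_pipeline

cfg = study_config(stages=("varpart",))
out = run_pipeline(cfg)

print("per-tract FW delta R^2 (percent, bootstrap mean and 95% CI):")
print(pd.read_csv(out / "varpart.csv").round(3).to_string(index=False))
print("\ntract-type ranking by mean delta R^2:")
print(pd.read_csv(out / "varpart_ranking.csv").round(3)
      .to_string(index=False))
print("\n(ANOVA/post-hoc on bootstrap replicates is anticonservative; "
      "read as a descriptive ranking.)")
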