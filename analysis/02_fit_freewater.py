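"""Validate the single-shell free-water fit on noiseless phantoms.

Runs the bi-tensor fit across a grid of ground-truth free-water fractions
and writes per-voxel recovery; the headline numbers are the median |f_hat
- f| over a 200-voxel grid and the fitted f in pure-water voxels.
"""

import pandas as pd

from common import study_config
from fwtrace.experiments import fw_recovery_experiment, fa_oracle
from fwtrace.pipeline import run_pipeline

cfg = study_config(stages=("fit-fw",))
out = run_pipeline(cfg)
rec = pd.read_csv(out / "fw_recovery.csv")
print(rec.round(4))

r = fw_recovery_experiment(seed=cfg.seed)
print(f"\n200-voxel noiseless grid: median |f_hat - f| = "
      f"{r['median_abs_error']:.2e}; pure-water voxels fit f >= "
      f"{r['water_f_min']:.4f}")
print(f"FA of the (1.7, 0.2, 0.2)e-3 tensor: {fa_oracle():.4f} "
      "(closed form 0.8704)")
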