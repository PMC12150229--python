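"""Longitudinal association scan: baseline white matter vs cognitive decline.

Per feature, a linear mixed model with interval, baseline age x interval
and WM x interval fixed effects and per-participant random intercept and
interval slope; the WM x interval term measures how strongly baseline
white matter predicts the rate of decline.
"""

import pandas as pd

from common import study_config
from fwtrace.pipeline import run_pipeline

cfg = study_config(stages=("scan-long",))
out = run_pipeline(cfg)

res = pd.read_csv(out / "scan_long.csv").sort_values("p")
print("top WM x interval associations:")
print(res.head(5)[["feature", "beta", "z", "p", "q"]].round(4)
      .to_string(index=False))
print(f"\nnon-converged models: {int((~res['converged']).sum())}; "
      f"{int((res['q'] < 0.05).sum())}/{len(res)} significant after FDR.")
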