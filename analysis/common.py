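"""Shared configuration for the numbered analysis drivers.

All drivers operate on one run directory under results/ so later stages
pick up earlier stages' outputs; the scale keeps a full pass at desk
scale (a few minutes on one CPU).
"""

import logging

from fwtrace.pipeline import PipelineConfig

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")


def study_config(**overrides) -> PipelineConfig:
    defaults = dict(out_dir="results/study_run", seed=7, scale=0.10,
                    n_boot=40)
    defaults.update(overrides)
    return PipelineConfig(**defaults)
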