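import numpy as np
import pytest

from fwtrace.synthetic import CohortConfig, default_truth, generate_study


def matched_cohorts(n, k=3, visits=2.5, gap=2.0, **kw):
    """k identically structured cohorts (one batch each) of n participants."""
    return [CohortConfig(name=f"C{i}", n_participants=n, age_mean=74.0,
                         age_sd=8.0, visit_count_mean=visits,
                         visit_interval_mean=gap,
                         diagnosis_mix={"CU": 0.7, "MCI": 0.2, "AD": 0.1},
                         apoe4_rate=0.3, **kw) for i in range(k)]


@pytest.fixture(scope="session")
def effect_study():
    """Moderate study with a fornix-FW effect and no batch shifts."""
    truth = default_truth(theta_wm_slope=-0.15, beta_wm_cross=-0.30,
                          gamma_batch={}, delta_batch={})
    feats = ["fornix_FW"] + [f"t{i}_FW" for i in range(5)]
    return generate_study(matched_cohorts(150, visits=3.0), truth, seed=42,
                          features=feats)


@pytest.fixture(scope="session")
def null_study():
    """Study with no white-matter effect and no batch shifts."""
    truth = default_truth(theta_wm_slope=0.0, beta_wm_cross=0.0,
                          gamma_batch={}, delta_batch={}, effect_features=())
    feats = [f"t{i}_FW" for i in range(6)]
    return generate_study(matched_cohorts(150, visits=3.0), truth, seed=7,
                          features=feats)
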