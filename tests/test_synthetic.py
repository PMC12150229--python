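"""Generator: cohort structure, determinism, effect and batch injection."""

import math

import numpy as np
import pandas as pd
import pytest

from fwtrace.synthetic import (CohortConfig, default_cohorts, default_truth,
                               generate_dwi_phantom, generate_study,
                               sphere_directions, tensor_from_eigs,
                               tensor_from_fa_md, WATER_DIFFUSIVITY)

from conftest import matched_cohorts


class TestStudyStructure:
    def test_published_cohort_sizes(self):
        """The default seven-cohort design reproduces the pooled study's
        participant counts (830/757/127/974/1160/326/293 = 4467)."""
        study = generate_study(seed=0, features=["fornix_FW"])
        counts = study.table.groupby("cohort")["participant_id"].nunique()
        expected = {"ADNI": 830, "BLSA": 757, "BIOCARD": 127, "NACC": 974,
                    "ROSMAPMARS": 1160, "VMAP": 326, "WRAP": 293}
        assert counts.to_dict() == expected
        assert counts.sum() == 4467

    def test_determinism(self):
        a = generate_study(matched_cohorts(30), seed=5, features=["t0_FW"])
        b = generate_study(matched_cohorts(30), seed=5, features=["t0_FW"])
        pd.testing.assert_frame_equal(a.table, b.table)
        c = generate_study(matched_cohorts(30), seed=6, features=["t0_FW"])
        assert not a.table["memory"].equals(c.table["memory"])

    def test_interval_definition(self):
        study = generate_study(matched_cohorts(40), seed=1, features=["t0_FW"])
        t = study.table
        assert np.allclose(t["interval"], t["age_at_visit"] - t["baseline_age"])
        assert (t["interval"] >= 0).all()
        assert (t.loc[t["visit_index"] == 0, "interval"] == 0).all()

    def test_marginal_structure(self):
        """Baseline age and visit counts match the configured means
        within 3 standard errors."""
        cfgs = matched_cohorts(400, k=1, visits=2.5)
        study = generate_study(cfgs, seed=3, features=["t0_FW"])
        base = study.table[study.table["visit_index"] == 0]
        age_se = cfgs[0].age_sd / math.sqrt(len(base))
        assert abs(base["baseline_age"].mean() - cfgs[0].age_mean) < 3 * age_se
        visits = study.table.groupby("participant_id").size()
        lam = cfgs[0].visit_count_mean - 1.0
        v_se = math.sqrt(lam / len(visits))
        assert abs(visits.mean() - cfgs[0].visit_count_mean) < 3 * v_se

    def test_batch_injection(self):
        """Pre-harmonization feature means differ across batches by the
        configured additive shifts within 3 SE."""
        truth = default_truth(gamma_batch={"batch_C0": 0.0, "batch_C1": 0.5},
                              delta_batch={}, effect_features=())
        study = generate_study(matched_cohorts(600, k=2), truth, seed=8,
                               features=["t0_FW"])
        t = study.table
        means = t.groupby("batch")["t0_FW"].mean()
        se = 2 * t["t0_FW"].std() / math.sqrt(t["participant_id"].nunique() / 2)
        assert abs((means["batch_C1"] - means["batch_C0"]) - 0.5) < 3 * se

    def test_null_slope_uncorrelated_with_baseline_feature(self):
        """With theta = 0 and no batch effects, per-participant cognitive
        slopes are uncorrelated with the baseline feature (permutation
        null bound)."""
        truth = default_truth(theta_wm_slope=0.0, beta_wm_cross=0.0,
                              gamma_batch={}, delta_batch={})
        study = generate_study(matched_cohorts(150, visits=3.0), truth,
                               seed=11, features=["fornix_FW"])
        t = study.table
        slopes, wm = [], []
        for pid, d in t.groupby("participant_id"):
            if len(d) >= 2 and d["interval"].max() > 0:
                slopes.append(np.polyfit(d["interval"], d["memory"], 1)[0])
                wm.append(d.sort_values("visit_index")["fornix_FW"].iloc[0])
        slopes, wm = np.asarray(slopes), np.asarray(wm)
        r_obs = abs(np.corrcoef(slopes, wm)[0, 1])
        rng = np.random.default_rng(0)
        null = [abs(np.corrcoef(slopes, rng.permutation(wm))[0, 1])
                for _ in range(1000)]
        assert r_obs < np.quantile(null, 0.975)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_participants"):
            CohortConfig("x", 0, 74, 8, 2, 2, {"CU": 1.0}, 0.3)
        with pytest.raises(ValueError, match="diagnosis_mix"):
            CohortConfig("x", 10, 74, 8, 2, 2, {"CU": 0.6, "MCI": 0.6}, 0.3)
        with pytest.raises(ValueError, match="non-empty"):
            generate_study([], seed=0)

    def test_default_cohorts_mirror_published_table(self):
        cfgs = {c.name: c for c in default_cohorts()}
        assert cfgs["ROSMAPMARS"].n_participants == 1160
        assert cfgs["WRAP"].age_mean == pytest.approx(62.01)
        assert cfgs["ADNI"].apoe4_rate == pytest.approx(0.357)
        for c in cfgs.values():
            assert sum(c.diagnosis_mix.values()) == pytest.approx(1.0)


class TestDWIPhantom:
    def test_pure_water_signal(self):
        """f = 1 gives S0 * exp(-b d_w) in every direction."""
        D = tensor_from_eigs([1.7e-3, 0.2e-3, 0.2e-3])
        ph = generate_dwi_phantom(1, 1.0, D, bval=1000, n_directions=16)
        dwi = ph.signals[0][ph.bvals > 0]
        assert np.allclose(dwi, 100.0 * math.exp(-1000 * WATER_DIFFUSIVITY))

    def test_water_diffusivity_degeneracy(self):
        """f = 0 with isotropic D at d_w is indistinguishable from f = 1."""
        ph0 = generate_dwi_phantom(1, 0.0,
                                   tensor_from_eigs([WATER_DIFFUSIVITY] * 3),
                                   bval=1000, n_directions=16)
        ph1 = generate_dwi_phantom(1, 1.0,
                                   tensor_from_eigs([1.7e-3, 2e-4, 2e-4]),
                                   bval=1000, n_directions=16)
        assert np.allclose(ph0.signals, ph1.signals)

    def test_forward_model_value_along_principal_axis(self):
        """f=0.3, eigenvalues (1.7, .2, .2)e-3, b=1000: the signal along the
        principal axis is S0 (0.7 e^-1.7 + 0.3 e^-3.0)."""
        dirs = sphere_directions(32)
        D = tensor_from_eigs([1.7e-3, 0.2e-3, 0.2e-3],
                             principal_direction=dirs[5])
        ph = generate_dwi_phantom(1, 0.3, D, bval=1000, n_directions=32)
        expected = 100.0 * (0.7 * math.exp(-1.7) + 0.3 * math.exp(-3.0))
        sig = ph.signals[0][ph.bvals > 0][5]
        assert sig == pytest.approx(expected, rel=1e-12)

    def test_rician_noise_and_truth_storage(self):
        D = tensor_from_fa_md(0.7, 0.7e-3)
        ph = generate_dwi_phantom(50, 0.2, D, snr=20, seed=3)
        assert ph.signals.min() > 0
        assert np.allclose(ph.f_true, 0.2)
        ph2 = generate_dwi_phantom(50, 0.2, D, snr=20, seed=3)
        assert np.array_equal(ph.signals, ph2.signals)

    def test_f_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            generate_dwi_phantom(2, [0.5, 1.2], tensor_from_fa_md(0.5, 7e-4))

    def test_directions_well_spread(self):
        dirs = sphere_directions(32)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        gram = dirs @ dirs.T - np.eye(32)
        assert gram.max() < 0.999       # no duplicated directions
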