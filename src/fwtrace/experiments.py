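"""Canonical validation experiments over the synthetic study.

Each function regenerates its inputs from a seed, runs one slice of the
pipeline, and returns the measured quantities.  The experiment designs
(cohort sizes, feature counts, bootstrap sizes) are fixed here so the test
suite, the analysis drivers and the acceptance script all measure the same
thing; docs/methods.md records why each size was chosen.
"""

from __future__ import annotations

import numpy as np

from .atlas import atlas_registry, feature_names, synthetic_atlas, METRICS
from .combat import PreserveDesign, apply_longcombat, fit_longcombat
from .features import extract_features
from .freewater import FitOptions, GradientTable, fit_bitensor, tensor_scalars
from .models import ModelSpec, longitudinal_scan
from .synthetic import (CohortConfig, default_truth, generate_dwi_phantom,
                        generate_study, tensor_from_fa_md, tensor_from_eigs)
from .varpart import bootstrap_delta_r2, fit_delta_r2, head_to_head

__all__ = [
    "feature_count_experiment",
    "fa_oracle",
    "fw_recovery_experiment",
    "harmonization_injection_experiment",
    "harmonization_coverage_experiment",
    "longitudinal_recovery_experiment",
    "longitudinal_null_experiment",
    "bootstrap_null_experiment",
    "head_to_head_experiment",
]

def _matched_cohorts(n: int, k: int = 3, visits: float = 2.5,
                     gap: float = 2.0) -> list[CohortConfig]:
    """k same-structure cohorts (one imaging batch each) of n participants."""
    return [CohortConfig(name=f"C{i}", n_participants=n, age_mean=74.0,
                         age_sd=8.0, visit_count_mean=visits,
                         visit_interval_mean=gap,
                         diagnosis_mix={"CU": 0.7, "MCI": 0.2, "AD": 0.1},
                         apoe4_rate=0.3) for i in range(k)]


# ---------------------------------------------------------------------------
# features / free water
# ---------------------------------------------------------------------------

def feature_count_experiment(seed: int = 0) -> int:
    """Extract one session over the packaged atlas: how many features?"""
    shape = (8, 8, 6)
    at = synthetic_atlas(shape, seed=seed)
    rng = np.random.default_rng(seed)
    maps = {m: rng.uniform(0.1, 0.9, shape) for m in METRICS}
    row = extract_features(maps, at, ("p0", 0))
    return len([c for c in row.columns
                if c not in ("participant_id", "session")])


def fa_oracle() -> float:
    """FA of the canonical prolate tensor (1.7, 0.2, 0.2) x 1e-3 mm^2/s."""
    from .freewater import FWFit
    fit = FWFit(f=0.0, D_tissue=tensor_from_eigs(
        np.array([1.7e-3, 0.2e-3, 0.2e-3])), s0=1.0, converged=True, n_iter=0)
    return tensor_scalars(fit).FAt


def fw_recovery_experiment(seed: int = 0,
                           n_water: int = 8) -> dict[str, float]:
    """Noiseless 200-voxel grid recovery plus pure-water voxels.

    The grid crosses f in {0, 0.1, ..., 0.8} with prolate tensors of
    FA in {0.1, ..., 0.8} at MD = 0.7e-3; n_water extra voxels contain
    only free water.
    """
    f_grid = np.repeat(np.arange(0.0, 0.81, 0.1), 23)[:200]
    fa_grid = np.tile(np.arange(0.1, 0.81, 0.1), 29)[:200]
    D = np.stack([tensor_from_fa_md(fa, 0.7e-3) for fa in fa_grid])
    ph = generate_dwi_phantom(200, f_grid, D, bval=1000.0, n_directions=32,
                              snr=None, seed=seed)
    gtab = GradientTable(ph.bvals, ph.bvecs)
    f_hat = np.array([fit_bitensor(s, gtab, FitOptions()).f
                      for s in ph.signals])
    err = np.abs(f_hat - f_grid)

    ph_w = generate_dwi_phantom(n_water, 1.0, D[:n_water], bval=1000.0,
                                n_directions=32, snr=None, seed=seed)
    gtab_w = GradientTable(ph_w.bvals, ph_w.bvecs)
    f_water = np.array([fit_bitensor(s, gtab_w, FitOptions()).f
                        for s in ph_w.signals])
    return {"median_abs_error": float(np.median(err)),
            "max_abs_error": float(err.max()),
            "water_f_min": float(f_water.min()),
            "n_voxels": 200}


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

_INJ_GAMMA = {"batch_C0": 0.0, "batch_C1": 0.1, "batch_C2": -0.2}
_INJ_DELTA = {"batch_C0": 1.0, "batch_C1": 2.0, "batch_C2": 1.0}


def harmonization_injection_experiment(seed: int = 0, n: int = 500,
                                       n_features: int = 40) -> dict[str, float]:
    """Recovery of injected batch effects, measured against a paired
    counterfactual.

    The same seed generates the study twice — once with the injected
    (gamma, delta) and once clean — so the injected component of every
    batch mean is known exactly (noise realizations are shared).  Reported:
    the pre/post reduction of the injected batch-mean gap and the
    post-harmonization within-subject variance ratio of the delta = 2
    batch against the others.
    """
    feats = [f"t{i}_FW" for i in range(n_features)]
    cohorts = _matched_cohorts(n)
    truth_inj = default_truth(gamma_batch=dict(_INJ_GAMMA),
                              delta_batch=dict(_INJ_DELTA), effect_features=())
    truth_clean = default_truth(gamma_batch={}, delta_batch={},
                                effect_features=())
    df = generate_study(cohorts, truth_inj, seed=seed, features=feats).table
    clean = generate_study(cohorts, truth_clean, seed=seed,
                           features=feats).table
    cols = ["participant_id", "batch", "age_at_visit", "sex",
            "baseline_diagnosis", "converter"] + feats
    model = fit_longcombat(df[cols], PreserveDesign(), feature_cols=feats)
    adj = apply_longcombat(df[cols], model)

    pre_gap, post_gap, ratios = [], [], []
    for col in feats:
        inj_pre = (df.groupby("batch")[col].mean()
                   - clean.groupby("batch")[col].mean())
        inj_post = (adj.groupby("batch")[col].mean()
                    - clean.groupby("batch")[col].mean())
        pre_gap.append((inj_pre - inj_pre.mean()).abs().max())
        post_gap.append((inj_post - inj_post.mean()).abs().max())
        r = adj[col] - adj.groupby(adj["participant_id"])[col].transform("mean")
        sd = r.groupby(adj["batch"]).std()
        ratios.append(float((sd["batch_C1"]
                             / sd[["batch_C0", "batch_C2"]].mean()) ** 2))
    reduction = 1.0 - float(np.mean(post_gap)) / float(np.mean(pre_gap))
    return {"gamma_reduction_pct": 100.0 * reduction,
            "variance_ratio_mean": float(np.mean(ratios)),
            "variance_ratio_max": float(np.max(ratios)),
            "variance_ratio_min": float(np.min(ratios)),
            "n_participants": 3 * n}


def harmonization_coverage_experiment(seed: int = 0, n_reps: int = 100,
                                      n: int = 60,
                                      n_features: int = 6) -> dict[str, float]:
    """Covariate preservation: how often does a 95% CI on the age slope of
    a harmonized feature cover the generating value?

    Per replicate a 3-batch study is generated with injected batch
    effects, harmonized, and the age slope of one feature re-estimated by
    OLS with cluster-robust (participant) standard errors.
    """
    import statsmodels.api as sm

    feats = [f"t{i}_FW" for i in range(n_features)]
    cols = ["participant_id", "batch", "age_at_visit", "sex",
            "baseline_diagnosis", "converter"] + feats
    truth = default_truth(gamma_batch=dict(_INJ_GAMMA),
                          delta_batch=dict(_INJ_DELTA), effect_features=())
    covered = 0
    used = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        df = generate_study(_matched_cohorts(n), truth, seed=rep_seed,
                            features=feats).table
        model = fit_longcombat(df[cols], PreserveDesign(),
                               feature_cols=feats)
        adj = apply_longcombat(df[cols], model)
        zage = (adj["age_at_visit"].to_numpy(float) - 74.3) / 9.2
        X = np.column_stack([np.ones(len(adj)), zage])
        fit = sm.OLS(adj[feats[0]].to_numpy(float), X).fit(
            cov_type="cluster",
            cov_kwds={"groups": adj["participant_id"].to_numpy()})
        lo, hi = fit.conf_int()[1]
        used += 1
        if lo <= truth.feature_age_slope <= hi:
            covered += 1
    return {"coverage_pct": 100.0 * covered / used, "n_reps": used}


# ---------------------------------------------------------------------------
# longitudinal scan
# ---------------------------------------------------------------------------

def longitudinal_recovery_experiment(seed: int = 0,
                                     n: int = 800) -> dict[str, float]:
    """Recovery of the generating WM x interval coefficient.

    n participants over 3 visits; theta = -0.15 on the fornix-FW analogue
    (the magnitude of the study's headline fornix association).
    """
    cohorts = _matched_cohorts(n // 2, k=2, visits=3.0)
    truth = default_truth(theta_wm_slope=-0.15, beta_wm_cross=-0.30,
                          gamma_batch={}, delta_batch={})
    df = generate_study(cohorts, truth, seed=seed,
                        features=["fornix_FW"]).table
    res = longitudinal_scan(df, ["fornix_FW"],
                            ModelSpec(scale_outcome=False,
                                      scale_features=False)).iloc[0]
    lo, hi = res.beta - 1.96 * res.se, res.beta + 1.96 * res.se
    return {"theta_hat": float(res.beta), "se": float(res.se),
            "ci_lo": float(lo), "ci_hi": float(hi),
            "covered": bool(lo <= truth.theta_wm_slope <= hi),
            "n_participants": int(res.n_participants)}


def longitudinal_null_experiment(seed: int = 0, n: int = 140,
                                 n_features: int | None = None) -> dict[str, float]:
    """Null calibration: with theta = 0 everywhere, what fraction of the
    full 240-feature scan stays non-significant after BH-FDR?"""
    feats = feature_names() if n_features is None \
        else feature_names()[:n_features]
    cohorts = _matched_cohorts(n, visits=3.0)
    truth = default_truth(theta_wm_slope=0.0, beta_wm_cross=0.0,
                          gamma_batch={}, delta_batch={}, effect_features=())
    df = generate_study(cohorts, truth, seed=seed, features=feats).table
    res = longitudinal_scan(df, feats, ModelSpec())
    ok = res["converged"]
    nonsig = float((res.loc[ok, "q"] >= 0.05).mean())
    return {"nonsignificant_pct": 100.0 * nonsig,
            "n_features": int(ok.sum())}


# ---------------------------------------------------------------------------
# bootstrap variance partitioning
# ---------------------------------------------------------------------------

def bootstrap_null_experiment(seed: int = 0, n: int = 500,
                              n_boot: int = 200) -> dict[str, float]:
    """Null delta R^2: theta = beta = 0; also the identity-resample check."""
    cohorts = _matched_cohorts(n // 2, k=2, visits=3.0)
    truth = default_truth(theta_wm_slope=0.0, beta_wm_cross=0.0,
                          gamma_batch={}, delta_batch={})
    df = generate_study(cohorts, truth, seed=seed,
                        features=["fornix_FW"]).table
    bd = bootstrap_delta_r2(df, "fornix", "FW", n_boot=n_boot, seed=seed)
    point, base, _ = fit_delta_r2(df, "fornix_FW")
    ident = bootstrap_delta_r2(df, "fornix", "FW", n_boot=2, seed=seed,
                               identity=True)
    return {"mean_delta_r2_pct": bd.mean,
            "ci_lo": bd.ci95[0], "ci_hi": bd.ci95[1],
            "base_r2_pct": bd.base_r2_mean,
            "identity_max_abs_diff": float(
                np.max(np.abs(ident.replicates - point))),
            "n_participants": bd.n_participants,
            "n_boot": bd.n_boot, "n_dropped": bd.n_dropped}


def head_to_head_experiment(seed: int = 0, n: int = 130, n_boot: int = 40,
                            tracts_per_type: int = 2) -> dict[str, object]:
    """Limbic-only slope effect: do limbic tracts rank first in mean
    delta R^2 when FW distributions are grouped by tract type?"""
    atlas = atlas_registry()
    tracts = []
    for ttype in atlas.types:
        tracts.extend([t.slug for t in atlas.by_type(ttype)][:tracts_per_type])
    limbic = tuple(f"{t.slug}_FW" for t in atlas.by_type("limbic"))
    feats = [f"{t}_FW" for t in tracts]
    truth = default_truth(theta_wm_slope=-0.15, beta_wm_cross=-0.30,
                          effect_features=limbic,
                          gamma_batch={}, delta_batch={})
    df = generate_study(_matched_cohorts(n, visits=3.0), truth, seed=seed,
                        features=feats).table
    dists = [bootstrap_delta_r2(df, t, "FW", n_boot=n_boot, seed=seed + i)
             for i, t in enumerate(tracts)]
    rep = head_to_head(dists, grouping="tract_type")
    ranking = rep.ranking
    top = ranking.iloc[0]["group"]
    limbic_mean = float(
        ranking.loc[ranking["group"] == "limbic", "mean_delta_r2"].iloc[0])
    best_other = float(
        ranking.loc[ranking["group"] != "limbic", "mean_delta_r2"].max())
    return {"top_group": str(top), "limbic_rank": int(
                ranking.index[ranking["group"] == "limbic"][0] + 1),
            "limbic_mean_delta_r2": limbic_mean,
            "best_other_mean_delta_r2": best_other,
            "ranking": ranking, "anova_f": rep.anova_f,
            "n_tracts": len(tracts), "n_boot": n_boot}
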