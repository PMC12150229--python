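"""Longitudinal ComBat batch harmonization.

Removes additive (gamma) and multiplicative (delta) imaging-batch effects
from longitudinal feature trajectories while preserving variance due to a
specified biological design (age, age^2, sex, baseline diagnosis, age x
converter, age^2 x converter by default) and subject-specific random
intercepts.

Per feature v the location-scale model is

    y_ivj = alpha_v + x_ivj' beta_v + gamma_bv + eta_iv + eps_ivj,
    Var(eps) = sigma_v^2 delta_bv^2,

estimated by a linear mixed model with batch as a fixed effect under an
n-weighted sum-to-zero constraint and a subject random intercept.  Batch
parameters are pooled across features within batch by parametric empirical
Bayes: gamma gets a normal prior whose shrinkage weights use each
estimate's own mixed-model sampling variance (noise-corrected
method-of-moments tau^2 — in longitudinal data the sampling noise of a
batch mean is dominated by between-subject variance, so row counts alone
would miscalibrate the shrinkage); delta^2 is estimated unbiasedly from
within-subject demeaned residuals and shrunk toward an inverse-gamma prior
with method-of-moments hyperparameters.  The adjusted data are

    y_adj = sigma_v * (z - gamma*_bv) / delta*_bv + alpha_v + x'beta_v + eta_iv

with z the standardized batch-containing residual.  Shrinkage needs a
cross-feature prior, so fewer than 5 features fall back to the unshrunken
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreserveDesign",
    "CombatModel",
    "fit_longcombat",
    "apply_longcombat",
]

_MIN_FEATURES_FOR_EB = 5


@dataclass
class PreserveDesign:
    """Biological covariates whose variance harmonization must preserve."""

    terms: tuple[str, ...] = ("age", "age2", "sex", "baseline_diagnosis",
                              "age_x_converter", "age2_x_converter")

    def build(self, table: pd.DataFrame) -> pd.DataFrame:
        """Numeric design matrix (no intercept) from a study table."""
        age = table["age_at_visit"].to_numpy(float)
        zage = (age - age.mean()) / (age.std(ddof=0) or 1.0)
        cols: dict[str, np.ndarray] = {}
        for term in self.terms:
            if term == "age":
                cols["age"] = zage
            elif term == "age2":
                cols["age2"] = zage ** 2
            elif term == "sex":
                cols["sex_male"] = (table["sex"].astype(str) == "male").astype(float).to_numpy()
            elif term == "baseline_diagnosis":
                dx = table["baseline_diagnosis"].astype(str)
                for level in ("MCI", "AD"):
                    cols[f"dx_{level}"] = (dx == level).astype(float).to_numpy()
            elif term == "age_x_converter":
                cols["age_x_converter"] = zage * table["converter"].to_numpy(float)
            elif term == "age2_x_converter":
                cols["age2_x_converter"] = zage ** 2 * table["converter"].to_numpy(float)
            else:
                raise ValueError(f"unknown preserve term {term!r}")
        return pd.DataFrame(cols, index=table.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.ones((len(X), 1))
        for name in X.columns:
            cand = np.column_stack([cur, X[name].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"preserve design is rank deficient; collinear "
                         f"terms: {bad}")


def _batch_coding(batch: pd.Series, batches: list[str],
                  counts: dict[str, int]) -> np.ndarray:
    """n-weighted sum-to-zero coding: columns for all but the last batch."""
    ref = batches[-1]
    cols = []
    for b in batches[:-1]:
        col = np.where(batch == b, 1.0,
                       np.where(batch == ref, -counts[b] / counts[ref], 0.0))
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(batch), 0))


@dataclass
class CombatModel:
    batch_col: str
    subject_col: str
    feature_cols: list[str]
    design_cols: list[str]
    batches: list[str]
    batch_counts: dict[str, int]
    beta: dict[str, np.ndarray] = field(default_factory=dict)        # incl. intercept
    sigma: dict[str, float] = field(default_factory=dict)
    subject_re_var: dict[str, float] = field(default_factory=dict)
    subject_effects: dict[str, dict] = field(default_factory=dict)   # feature -> {subject: eta}
    gamma_hat: pd.DataFrame | None = None       # z-scale, batches x features
    delta_hat: pd.DataFrame | None = None
    gamma_star: pd.DataFrame | None = None
    delta_star: pd.DataFrame | None = None
    hyper: dict[str, dict] = field(default_factory=dict)             # batch -> EB hyperparams

    @property
    def gamma_star_data(self) -> pd.DataFrame:
        """Shrunken additive batch effects on the original data scale."""
        sig = pd.Series(self.sigma)
        return self.gamma_star.mul(sig, axis=1)


def _fit_one_feature(y, X, batch_mat, groups):
    """Mixed model y ~ 1 + X + batch with subject random intercept.

    Returns (beta incl. intercept and batch coefs, covariance of the batch
    coefficients, eta per subject, sigma, random-intercept variance).
    Falls back to OLS when the mixed fit is degenerate (e.g. noise-free
    data).
    """
    from .lmm import fit_lmm

    exog = np.column_stack([np.ones(len(y)), X, batch_mat])
    k_batch = batch_mat.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lmm(y, exog, groups)
        if not np.isfinite(res.sigma2) or res.sigma2 <= 1e-12:
            raise ValueError("degenerate scale")
        # closed-form random-intercept BLUPs
        tau2 = float(res.psi[0, 0])
        resid = y - exog @ res.beta
        eta = {}
        for g in np.unique(groups):
            sel = groups == g
            n_i = int(sel.sum())
            shrink = tau2 * n_i / (res.sigma2 + tau2 * n_i)
            eta[g] = float(shrink * resid[sel].mean())
        cov_b = res.cov_beta[-k_batch:, -k_batch:] if k_batch \
            else np.empty((0, 0))
        return (res.beta, cov_b, eta, float(np.sqrt(res.sigma2)), tau2)
    except Exception:
        coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
        resid = y - exog @ coef
        dof = max(len(y) - exog.shape[1], 1)
        sigma2 = float(np.sum(resid ** 2) / dof)
        xtx_inv = np.linalg.pinv(exog.T @ exog)
        cov_b = sigma2 * xtx_inv[-k_batch:, -k_batch:] if k_batch else np.empty((0, 0))
        return np.asarray(coef), cov_b, {}, float(np.sqrt(sigma2)), 0.0


def fit_longcombat(features: pd.DataFrame,
                   design: pd.DataFrame | PreserveDesign,
                   batch_col: str = "batch",
                   subject_col: str = "participant_id",
                   feature_cols: list[str] | None = None) -> CombatModel:
    """Estimate the longitudinal ComBat model on a feature matrix.

    ``design`` is either a numeric covariate DataFrame aligned with
    ``features`` (no intercept column) or a :class:`PreserveDesign`, which
    is built from the feature table itself.
    """
    if isinstance(design, PreserveDesign):
        design = design.build(features)
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c not in (batch_col, subject_col)
                        and c not in design.columns
                        and pd.api.types.is_numeric_dtype(features[c])]
    batch = features[batch_col].astype(str)
    batches = sorted(batch.unique())
    if len(batches) < 2:
        raise ValueError("need >= 2 batches to harmonize")
    subj_per_batch = features.groupby(batch)[subject_col].nunique()
    lonely = subj_per_batch[subj_per_batch < 2]
    if len(lonely):
        raise ValueError(f"batches with a single subject cannot be "
                         f"harmonized: {list(lonely.index)}")
    _check_full_rank(design)

    counts = batch.value_counts().to_dict()
    batch_mat = _batch_coding(batch, batches, counts)
    Xmat = design.to_numpy(float)
    groups = features[subject_col].to_numpy()

    model = CombatModel(batch_col=batch_col, subject_col=subject_col,
                        feature_cols=list(feature_cols),
                        design_cols=list(design.columns),
                        batches=batches, batch_counts=counts)

    n_design = Xmat.shape[1]
    gamma_hat = pd.DataFrame(index=batches, columns=feature_cols, dtype=float)
    gamma_var = pd.DataFrame(index=batches, columns=feature_cols, dtype=float)
    delta_hat = pd.DataFrame(index=batches, columns=feature_cols, dtype=float)
    bvals = batch.to_numpy()

    # within-subject degrees of freedom per batch (structure is shared by
    # all features); subjects with a single session contribute nothing
    subj_codes, subj_idx = np.unique(groups, return_inverse=True)
    subj_batch = {}
    for k, sc in enumerate(subj_codes):
        subj_batch[k] = bvals[subj_idx == k][0]
    dof_b = {b: 0 for b in batches}
    for k in range(len(subj_codes)):
        n_i = int((subj_idx == k).sum())
        if n_i >= 2:
            dof_b[subj_batch[k]] += n_i - 1

    # weights expressing the reference batch's effect under the coding
    w_ref = np.array([-counts[b] / counts[batches[-1]] for b in batches[:-1]])

    for col in feature_cols:
        y = features[col].to_numpy(float)
        coef, cov_b, eta, sigma, re_var = _fit_one_feature(
            y, Xmat, batch_mat, groups)
        beta = coef[: 1 + n_design]
        gcoef = coef[1 + n_design:]
        g_all = np.append(gcoef, w_ref @ gcoef if len(gcoef) else 0.0)
        v_all = np.append(np.diag(cov_b), float(w_ref @ cov_b @ w_ref)
                          if cov_b.size else 0.0)
        if sigma <= 1e-10:
            sigma = 1.0
        eta_row = np.array([eta.get(g, 0.0) for g in groups])
        r = y - beta[0] - Xmat @ beta[1:]          # keeps gamma + eta + eps
        z = (r - eta_row) / sigma
        model.beta[col] = beta
        model.sigma[col] = sigma
        model.subject_re_var[col] = re_var
        model.subject_effects[col] = eta
        # unbiased within-subject residual variance per batch
        r_centered = r - np.bincount(subj_idx, weights=r)[subj_idx] \
            / np.bincount(subj_idx)[subj_idx]
        for k, b in enumerate(batches):
            gamma_hat.loc[b, col] = g_all[k] / sigma
            gamma_var.loc[b, col] = max(v_all[k], 1e-12) / sigma ** 2
            if dof_b[b] > 0:
                ssq = float(np.sum(r_centered[bvals == b] ** 2))
                d2 = ssq / dof_b[b] / sigma ** 2
            else:       # no repeated sessions in this batch: residual-based
                eps = z[bvals == b] - g_all[k] / sigma
                d2 = eps.var(ddof=1) if (bvals == b).sum() > 1 else 1.0
            delta_hat.loc[b, col] = np.sqrt(d2) if d2 > 1e-12 else 1.0

    model.gamma_hat = gamma_hat
    model.delta_hat = delta_hat

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    if len(feature_cols) >= _MIN_FEATURES_FOR_EB:
        for b in batches:
            g = gamma_hat.loc[b].to_numpy(float)
            v = gamma_var.loc[b].to_numpy(float)
            d2 = delta_hat.loc[b].to_numpy(float) ** 2
            # normal prior on gamma; shrinkage weighted by each estimate's
            # sampling variance, tau^2 by noise-corrected method of moments
            gbar = float(np.average(g, weights=1.0 / v))
            t2 = max(float(g.var(ddof=1)) - float(v.mean()), 0.0)
            gamma_star.loc[b] = (t2 * g + v * gbar) / (t2 + v)
            # inverse-gamma prior on delta^2, method-of-moments hyperparams
            m, s2 = float(d2.mean()), float(d2.var(ddof=1))
            a_prior = (2 * s2 + m ** 2) / s2 if s2 > 1e-12 else 100.0
            b_prior = (m * s2 + m ** 3) / s2 if s2 > 1e-12 else m * 99.0
            nu = max(dof_b[b], 2)
            d2_star = (b_prior + 0.5 * nu * d2) / (nu / 2 + a_prior - 1)
            delta_star.loc[b] = np.sqrt(np.clip(d2_star, 1e-12, None))
            model.hyper[b] = {"gamma_bar": gbar, "tau2": t2,
                              "a_prior": a_prior, "b_prior": b_prior}
    model.gamma_star, model.delta_star = gamma_star, delta_star
    return model


def apply_longcombat(features: pd.DataFrame, model: CombatModel,
                     design: pd.DataFrame | PreserveDesign | None = None
                     ) -> pd.DataFrame:
    """Adjust a feature matrix with a fitted model.

    Output schema is identical to the input; only the model's feature
    columns change.  Batches unseen at fit time raise (no reference-batch
    imputation); subjects unseen at fit time get a zero random effect.
    """
    if design is None:
        design = PreserveDesign()
    if isinstance(design, PreserveDesign):
        design = design.build(features)
    if list(design.columns) != model.design_cols:
        raise ValueError("design columns differ from the fitted model")
    batch = features[model.batch_col].astype(str)
    unseen = sorted(set(batch) - set(model.batches))
    if unseen:
        raise ValueError(f"batches unseen at fit time: {unseen}")

    out = features.copy()
    Xmat = design.to_numpy(float)
    groups = features[model.subject_col].to_numpy()
    bvals = batch.to_numpy()
    for col in model.feature_cols:
        beta = model.beta[col]
        sigma = model.sigma[col]
        eta = model.subject_effects[col]
        eta_row = np.array([eta.get(g, 0.0) for g in groups])
        fitted = beta[0] + Xmat @ beta[1:] + eta_row
        z = (features[col].to_numpy(float) - fitted) / sigma
        g_star = model.gamma_star[col].reindex(bvals).to_numpy(float)
        d_star = model.delta_star[col].reindex(bvals).to_numpy(float)
        out[col] = sigma * (z - g_star) / d_star + fitted
    return out
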