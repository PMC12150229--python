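"""Association scans: demographic comparisons, per-tract regressions,
longitudinal mixed models, endophenotype interactions, and FDR control.

Cross-sectional scans fit, per tract x metric feature, an OLS of a
cognitive composite on the scaled baseline feature plus covariates (age,
education, sex, race/ethnicity, baseline clinical status, APOE e4/e2) and
report the feature term's standardized beta.  Longitudinal scans fit a
linear mixed model with the same covariates plus interval, baseline age x
interval and baseline feature x interval, with a per-participant random
intercept and interval slope, and report the feature x interval term —
the association between baseline white matter and the rate of cognitive
change.  Interaction scans add an endophenotype and its products with the
feature (and, longitudinally, with interval), always keeping every
lower-order term.  p-values within a scan family are converted to
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "DEFAULT_COVARIATES",
    "compare_demographics",
    "cross_sectional_scan",
    "longitudinal_scan",
    "interaction_scan",
    "fdr_adjust",
]

DEFAULT_COVARIATES = ("baseline_age", "education", "sex", "race_ethnicity",
                      "baseline_diagnosis", "apoe4", "apoe2")

_CATEGORICAL_REFERENCE = {"sex": "female", "baseline_diagnosis": "CU",
                          "race_ethnicity": "NH White"}


@dataclass
class ModelSpec:
    """What one scan fits: outcome, covariates, and optional extras."""

    outcome: str = "memory"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    endophenotype: str | None = None
    scale_outcome: bool = True
    scale_features: bool = True
    random_slope: bool = True


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# demographics decision tree
# ---------------------------------------------------------------------------

def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F*, p)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    b = 1.0 + (2.0 * (k - 2) / (k ** 2 - 1)) * np.sum(
        (1.0 - w / np.sum(w)) ** 2 / (n - 1))
    f = a / b
    df2 = (k ** 2 - 1) / (3.0 * np.sum((1.0 - w / np.sum(w)) ** 2 / (n - 1)))
    return float(f), float(stats.f.sf(f, k - 1, df2))


def compare_demographics(table: pd.DataFrame, group_col: str = "cohort",
                         variables: list[str] | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Between-group comparison routed by distributional checks.

    Continuous variables: Shapiro-Wilk normality per group; if all groups
    pass, Levene's test decides between classical ANOVA (equal variances)
    and Welch ANOVA; otherwise Kruskal-Wallis.  Categorical variables:
    chi-square, or Fisher's exact test when an expected cell count is low
    (< 5) and the table is 2x2.  Constant variables are reported as
    untestable rather than raising.
    """
    if variables is None:
        variables = [c for c in table.columns if c != group_col]
    group_labels = table[group_col].unique()
    if len(group_labels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for var in variables:
        col = table[var].dropna()
        grouped = [table.loc[table[group_col] == g, var].dropna()
                   for g in group_labels]
        if col.nunique() <= 1:
            rows.append((var, "untestable (constant)", np.nan, np.nan))
            continue
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 5:
            arrs = [np.asarray(g, dtype=float) for g in grouped]
            # Shapiro-Wilk caps at 5000 observations; subsample determinstically
            normal = True
            for a in arrs:
                a = a[:5000]
                if len(a) >= 3 and stats.shapiro(a).pvalue < alpha:
                    normal = False
                    break
            if not normal:
                stat, p = stats.kruskal(*arrs)
                rows.append((var, "Kruskal-Wallis", float(stat), float(p)))
            elif stats.levene(*arrs, center="median").pvalue < alpha:
                f, p = _welch_anova(arrs)
                rows.append((var, "Welch ANOVA", f, p))
            else:
                stat, p = stats.f_oneway(*arrs)
                rows.append((var, "ANOVA", float(stat), float(p)))
        else:
            ct = pd.crosstab(table[var], table[group_col])
            expected = stats.contingency.expected_freq(ct.to_numpy())
            if (expected < 5).any() and ct.shape == (2, 2):
                _, p = stats.fisher_exact(ct.to_numpy())
                rows.append((var, "Fisher exact", np.nan, float(p)))
            else:
                res = stats.chi2_contingency(ct.to_numpy())
                rows.append((var, "chi-square", float(res.statistic),
                             float(res.pvalue)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def build_covariates(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate block: z-scored continuous, dummy-coded categorical.

    Reference levels: CU, female, NH White, APOE e4/e2 non-carrier.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        s = df[cov]
        if cov in _CATEGORICAL_REFERENCE or not pd.api.types.is_numeric_dtype(s):
            ref = _CATEGORICAL_REFERENCE.get(cov)
            levels = [lv for lv in pd.unique(s.astype(str)) if lv != ref]
            for lv in sorted(levels):
                cols[f"{cov}[{lv}]"] = (s.astype(str) == lv).astype(float).to_numpy()
        elif s.nunique() <= 2:
            cols[cov] = s.astype(float).to_numpy()
        else:
            cols[cov] = _zscore(s.astype(float).to_numpy())
    return pd.DataFrame(cols, index=df.index)


@dataclass
class _TermResult:
    feature: str
    term: str
    beta: float
    se: float
    z: float
    p: float
    n_obs: int
    n_participants: int
    converged: bool


def _results_frame(results: list[_TermResult], fdr_pool: bool = True) -> pd.DataFrame:
    out = pd.DataFrame([r.__dict__ for r in results])
    out["q"] = np.nan
    ok = out["converged"] & np.isfinite(out["p"])
    if ok.any():
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# cross-sectional scan
# ---------------------------------------------------------------------------

def cross_sectional_scan(baseline: pd.DataFrame, features: list[str],
                         spec: ModelSpec | None = None) -> pd.DataFrame:
    """Per-feature OLS of a cognitive composite at baseline.

    ``baseline`` must hold one row per participant.  Returns a tidy frame
    with the feature term's standardized beta, z, p and BH q per feature.
    """
    spec = spec or ModelSpec()
    if baseline["participant_id"].duplicated().any():
        raise ValueError("baseline table must have one row per participant")
    X_cov = build_covariates(baseline, spec.covariates)
    y = baseline[spec.outcome].astype(float).to_numpy()
    if spec.scale_outcome:
        y = _zscore(y)
    results = []
    for feat in features:
        x = baseline[feat].astype(float).to_numpy()
        if spec.scale_features:
            x = _zscore(x)
        exog = np.column_stack([np.ones(len(y)), x, X_cov.to_numpy()])
        ok = np.all(np.isfinite(exog), axis=1) & np.isfinite(y)
        try:
            if np.linalg.matrix_rank(exog[ok]) < exog.shape[1]:
                raise np.linalg.LinAlgError("singular design")
            fit = sm.OLS(y[ok], exog[ok]).fit()
            results.append(_TermResult(feat, "wm", float(fit.params[1]),
                                       float(fit.bse[1]),
                                       float(fit.params[1] / fit.bse[1]),
                                       float(fit.pvalues[1]), int(ok.sum()),
                                       int(ok.sum()), True))
        except Exception:
            results.append(_TermResult(feat, "wm", np.nan, np.nan, np.nan,
                                       np.nan, int(ok.sum()), int(ok.sum()),
                                       False))
    return _results_frame(results)


# ---------------------------------------------------------------------------
# longitudinal scan
# ---------------------------------------------------------------------------

def _fit_mixed(y, exog, groups, interval, random_slope, report_idx):
    """Mixed model with random intercept + interval slope; Wald z inference.

    Non-convergence falls back to a random intercept only.  Estimation uses
    the package's profiled-REML solver (:mod:`fwtrace.lmm`).
    """
    from .lmm import fit_lmm
    zs = [np.column_stack([np.ones(len(y)), interval])] if random_slope else []
    zs.append(np.ones((len(y), 1)))
    for Z in zs:
        try:
            res = fit_lmm(y, exog, groups, Z=Z, reml=True)
            beta = float(res.beta[report_idx])
            se = float(res.se[report_idx])
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                continue
            z = beta / se
            return beta, se, z, float(2 * stats.norm.sf(abs(z))), res, True
        except Exception:
            continue
    return np.nan, np.nan, np.nan, np.nan, None, False


def _longitudinal_design(df, feat, spec, endophenotype=None):
    """Fixed-effects design for one feature's longitudinal model.

    Columns: covariates at baseline, baseline WM, interval, baseline age x
    interval, WM x interval, and (optionally) the endophenotype block with
    every lower-order term of the 3-way WM x endo x interval product.
    Returns (y, exog, groups, interval, report_idx, colnames).
    """
    base = df[df["visit_index"] == 0][["participant_id", feat]].rename(
        columns={feat: "_wm0"})
    d = df.merge(base, on="participant_id", how="inner")
    y = d[spec.outcome].astype(float).to_numpy()
    if spec.scale_outcome:
        y = _zscore(y)
    X_cov = build_covariates(d, spec.covariates)
    wm0 = d["_wm0"].astype(float).to_numpy()
    if spec.scale_features:
        wm0 = _zscore(wm0)
    t = d["interval"].astype(float).to_numpy()
    if t.max() <= 0:
        raise ValueError("all intervals are zero: longitudinal terms "
                         "(wm x interval) are inestimable with one visit "
                         "per participant")
    age0 = _zscore(d["baseline_age"].astype(float).to_numpy())
    cols = {"wm0": wm0, "interval": t, "age0_x_interval": age0 * t,
            "wm0_x_interval": wm0 * t}
    report = "wm0_x_interval"
    if endophenotype is not None:
        e = d[endophenotype].astype(float).to_numpy()
        if np.nanstd(e) == 0:
            raise ValueError(f"endophenotype {endophenotype!r} is constant; "
                             "interaction inestimable")
        if set(np.unique(e[np.isfinite(e)])) - {0.0, 1.0} != set():
            e = _zscore(e)
        cols.update({"endo": e, "wm0_x_endo": wm0 * e,
                     "endo_x_interval": e * t,
                     "wm0_x_endo_x_interval": wm0 * e * t})
        report = "wm0_x_endo_x_interval"
    names = list(cols)
    exog = np.column_stack([np.ones(len(y))] + [cols[c] for c in names]
                           + [X_cov.to_numpy()])
    report_idx = 1 + names.index(report)
    return y, exog, d["participant_id"].to_numpy(), t, report_idx, names


def longitudinal_scan(df: pd.DataFrame, features: list[str],
                      spec: ModelSpec | None = None) -> pd.DataFrame:
    """Per-feature linear mixed model of cognitive change.

    Reports the baseline-WM x interval term: how strongly baseline white
    matter predicts the annual rate of cognitive decline.
    """
    spec = spec or ModelSpec()
    results = []
    for feat in features:
        y, exog, groups, t, ridx, _ = _longitudinal_design(df, feat, spec)
        beta, se, z, p, res, conv = _fit_mixed(
            y, exog, groups, t, spec.random_slope, ridx)
        results.append(_TermResult(feat, "wm0_x_interval", beta, se, z, p,
                                   len(y), len(np.unique(groups)), conv))
    return _results_frame(results)


def interaction_scan(df: pd.DataFrame, features: list[str],
                     endophenotype: str, mode: str = "longitudinal",
                     spec: ModelSpec | None = None) -> pd.DataFrame:
    """White matter x endophenotype interaction models.

    Cross-sectional mode reports the 2-way WM x endophenotype term on
    baseline cognition; longitudinal mode reports the 3-way WM x
    endophenotype x interval term on cognitive change.  All lower-order
    terms are always included.
    """
    spec = spec or ModelSpec()
    if mode not in ("cross-sectional", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    e_all = df[endophenotype]
    if e_all.nunique() <= 1:
        raise ValueError(f"endophenotype {endophenotype!r} has a single "
                         "level; interaction inestimable")
    results = []
    if mode == "cross-sectional":
        baseline = df[df["visit_index"] == 0]
        X_cov = build_covariates(baseline, spec.covariates)
        y = baseline[spec.outcome].astype(float).to_numpy()
        if spec.scale_outcome:
            y = _zscore(y)
        e = baseline[endophenotype].astype(float).to_numpy()
        if set(np.unique(e[np.isfinite(e)])) - {0.0, 1.0} != set():
            e = _zscore(e)
        for feat in features:
            x = baseline[feat].astype(float).to_numpy()
            if spec.scale_features:
                x = _zscore(x)
            exog = np.column_stack([np.ones(len(y)), x, e, x * e,
                                    X_cov.to_numpy()])
            ok = np.all(np.isfinite(exog), axis=1) & np.isfinite(y)
            try:
                if np.linalg.matrix_rank(exog[ok]) < exog.shape[1]:
                    raise np.linalg.LinAlgError("singular design")
                fit = sm.OLS(y[ok], exog[ok]).fit()
                results.append(_TermResult(feat, "wm_x_endo",
                                           float(fit.params[3]),
                                           float(fit.bse[3]),
                                           float(fit.params[3] / fit.bse[3]),
                                           float(fit.pvalues[3]),
                                           int(ok.sum()), int(ok.sum()), True))
            except Exception:
                results.append(_TermResult(feat, "wm_x_endo", np.nan, np.nan,
                                           np.nan, np.nan, int(ok.sum()),
                                           int(ok.sum()), False))
    else:
        for feat in features:
            y, exog, groups, t, ridx, _ = _longitudinal_design(
                df, feat, spec, endophenotype=endophenotype)
            beta, se, z, p, res, conv = _fit_mixed(
                y, exog, groups, t, spec.random_slope, ridx)
            results.append(_TermResult(feat, "wm0_x_endo_x_interval", beta,
                                       se, z, p, len(y),
                                       len(np.unique(groups)), conv))
    return _results_frame(results)
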