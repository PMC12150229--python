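"""Bootstrapped head-to-head comparison of white-matter features.

For each tract x metric, the marginal variance a white-matter feature adds
to a longitudinal model of cognitive decline is quantified as

    delta R^2 = R^2_marginal(covariates + WM) - R^2_marginal(covariates)

where the marginal R^2 of a mixed model is the Nakagawa-Schielzeth
proportion var(fixed predictions) / (var(fixed) + random variances +
residual variance), with the random-slope extension (the random variance
averages z_ij' Psi z_ij over observations).  Distributions are obtained by
a cluster bootstrap: participants are resampled with replacement
(stratified by cohort so the design composition is preserved) and all of a
participant's visits move together.  Groups of distributions (by metric,
tract type or tract) are compared by one-way ANOVA with pairwise Welch
t tests and BH-FDR over pairs; treating bootstrap replicates as
observations is anticonservative and reports carry that caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import atlas_registry
from .models import ModelSpec, build_covariates, fdr_adjust, _zscore

__all__ = [
    "BootstrapDistribution",
    "HeadToHeadReport",
    "marginal_r2",
    "fit_delta_r2",
    "bootstrap_delta_r2",
    "head_to_head",
]

ANTICONSERVATIVE_CAVEAT = (
    "Bootstrap replicates are treated as independent observations in the "
    "ANOVA/post-hoc comparisons; the resulting p-values are anticonservative "
    "and should be read as descriptive rankings.")


def marginal_r2(fixed_var: float, random_vars: float, resid_var: float) -> float:
    """Nakagawa-Schielzeth marginal R^2 from variance components."""
    if fixed_var < 0 or random_vars < 0 or resid_var < 0:
        raise ValueError("variances must be non-negative")
    total = fixed_var + random_vars + resid_var
    if total <= 0:
        raise ValueError("all variance components are zero; R^2 undefined")
    return fixed_var / total


def _design(df: pd.DataFrame, outcome: str, covariates, feature: str | None):
    """Long-format design: covariates, interval, age0 x interval, and —
    when ``feature`` is given — baseline WM and WM x interval."""
    y = df[outcome].astype(float).to_numpy()
    t = df["interval"].astype(float).to_numpy()
    age0 = _zscore(df["baseline_age"].astype(float).to_numpy())
    X_cov = build_covariates(df, covariates)
    blocks = [np.ones(len(y))[:, None], t[:, None], (age0 * t)[:, None],
              X_cov.to_numpy()]
    if feature is not None:
        base = df[df["visit_index"] == 0][["participant_id", feature]]
        wm0 = df["participant_id"].map(
            base.set_index("participant_id")[feature]).astype(float).to_numpy()
        wm0 = _zscore(wm0)
        blocks.insert(1, (wm0 * t)[:, None])
        blocks.insert(1, wm0[:, None])
    exog = np.column_stack(blocks)
    return y, exog, df["participant_id"].to_numpy(), t


def _r2_mixed(y, exog, groups, t, random_slope=True,
              theta0=None) -> tuple[float, np.ndarray] | None:
    """(marginal R^2, warm-start params) of one mixed fit; None on failure."""
    from .lmm import fit_lmm, theta_from_psi
    Z = np.column_stack([np.ones(len(y)), t]) if random_slope \
        else np.ones((len(y), 1))
    try:
        res = fit_lmm(y, exog, groups, Z=Z, reml=True, theta0=theta0)
        if not np.all(np.isfinite(res.beta)):
            return None
        fixed = exog @ res.beta
        vf = float(fixed.var())
        psi = res.psi
        if random_slope:
            vr = float(np.mean(psi[0, 0] + 2 * psi[0, 1] * t
                               + psi[1, 1] * t ** 2))
        else:
            vr = float(psi[0, 0])
        return (marginal_r2(vf, max(vr, 0.0), res.sigma2),
                theta_from_psi(psi, res.sigma2))
    except Exception:
        return None


def _fit_delta_r2(df, feature, spec, thetas=(None, None)):
    yb, xb, gb, tb = _design(df, spec.outcome, spec.covariates, None)
    yf, xf, gf, tf = _design(df, spec.outcome, spec.covariates, feature)
    rb = _r2_mixed(yb, xb, gb, tb, spec.random_slope, theta0=thetas[0])
    rf = _r2_mixed(yf, xf, gf, tf, spec.random_slope, theta0=thetas[1])
    if rb is None or rf is None:
        raise RuntimeError("mixed model did not converge")
    (r2b, th_b), (r2f, th_f) = rb, rf
    return 100.0 * (r2f - r2b), 100.0 * r2b, 100.0 * r2f, (th_b, th_f)


def fit_delta_r2(df: pd.DataFrame, feature: str,
                 spec: ModelSpec | None = None) -> tuple[float, float, float]:
    """Point estimate (delta R^2 %, base R^2 %, full R^2 %) on one dataset."""
    spec = spec or ModelSpec()
    d, b, f, _ = _fit_delta_r2(df, feature, spec)
    return d, b, f


@dataclass
class BootstrapDistribution:
    tract: str
    metric: str
    domain: str
    replicates: np.ndarray          # delta R^2, percent scale
    n_boot: int
    mean: float
    ci95: tuple[float, float]
    base_r2_mean: float
    base_r2_ci: tuple[float, float]
    n_participants: int
    n_dropped: int = 0

    @classmethod
    def summarize(cls, tract, metric, domain, deltas, base_r2s,
                  n_participants, n_dropped):
        deltas = np.asarray(deltas, dtype=float)
        base = np.asarray(base_r2s, dtype=float)
        return cls(
            tract=tract, metric=metric, domain=domain, replicates=deltas,
            n_boot=len(deltas), mean=float(deltas.mean()),
            ci95=(float(np.percentile(deltas, 2.5)),
                  float(np.percentile(deltas, 97.5))),
            base_r2_mean=float(base.mean()),
            base_r2_ci=(float(np.percentile(base, 2.5)),
                        float(np.percentile(base, 97.5))),
            n_participants=n_participants, n_dropped=n_dropped)


def bootstrap_delta_r2(df: pd.DataFrame, tract: str, metric: str,
                       spec: ModelSpec | None = None,
                       n_boot: int = 1000, seed: int = 0,
                       identity: bool = False,
                       stratify: str = "cohort",
                       strict: bool = False) -> BootstrapDistribution:
    """Cluster-bootstrap distribution of delta R^2 for one tract x metric.

    Participants are resampled with replacement within ``stratify`` strata;
    every visit of a drawn participant enters the replicate.  With
    ``identity=True`` each replicate is the original sample (testing hook:
    the distribution collapses onto the point estimate).  Non-converged
    replicates are dropped and counted; above 20% dropped a warning is
    raised, escalated to an error under ``strict``.
    """
    spec = spec or ModelSpec()
    feature = f"{tract}_{metric}"
    if feature not in df.columns:
        raise KeyError(f"feature column {feature!r} not in table")
    rng = np.random.default_rng(seed)
    pids = df["participant_id"].unique()
    strata = (df.drop_duplicates("participant_id")
              .set_index("participant_id")[stratify]) if stratify else None
    row_idx = {p: np.flatnonzero(df["participant_id"].to_numpy() == p)
               for p in pids}

    # point fit supplies warm starts for every replicate refit
    try:
        d_point, b_point, _, thetas = _fit_delta_r2(df, feature, spec)
    except RuntimeError as exc:
        raise RuntimeError(
            f"mixed model did not converge on the full data for {feature}"
        ) from exc

    deltas, bases = [], []
    n_dropped = 0
    for rep in range(n_boot):
        if identity:
            # the identity resample is, by definition, the point computation
            deltas.append(d_point)
            bases.append(b_point)
            continue
        else:
            drawn = []
            if strata is not None:
                for s, members in strata.groupby(strata).groups.items():
                    members = np.asarray(list(members))
                    drawn.append(rng.choice(members, size=len(members),
                                            replace=True))
                drawn = np.concatenate(drawn)
            else:
                drawn = rng.choice(pids, size=len(pids), replace=True)
            rows = np.concatenate([row_idx[p] for p in drawn])
            new_ids = np.repeat(np.arange(len(drawn)),
                                [len(row_idx[p]) for p in drawn])
            sample = df.iloc[rows].copy()
            sample["participant_id"] = new_ids
        try:
            d, b, _, _ = _fit_delta_r2(sample, feature, spec, thetas)
            deltas.append(d)
            bases.append(b)
        except RuntimeError:
            n_dropped += 1
    if n_boot and n_dropped > 0.2 * n_boot:
        msg = (f"{n_dropped}/{n_boot} bootstrap replicates failed to "
               f"converge for {feature}")
        if strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
    if not deltas:
        raise RuntimeError(f"no converged bootstrap replicates for {feature}")
    return BootstrapDistribution.summarize(
        tract, metric, spec.outcome, deltas, bases, len(pids), n_dropped)


@dataclass
class HeadToHeadReport:
    grouping: str
    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame           # pairwise Welch t with BH q
    ranking: pd.DataFrame           # groups sorted by mean delta R^2
    caveat: str = ANTICONSERVATIVE_CAVEAT


def head_to_head(distributions: list[BootstrapDistribution],
                 grouping: str = "metric") -> HeadToHeadReport:
    """Compare delta R^2 distributions grouped by metric, tract type or tract."""
    if grouping not in ("metric", "tract_type", "tract"):
        raise ValueError(f"unknown grouping {grouping!r}")
    atlas = atlas_registry()
    type_of = {t.slug: t.tract_type for t in atlas}

    def key(d: BootstrapDistribution) -> str:
        if grouping == "metric":
            return d.metric
        if grouping == "tract":
            return d.tract
        return type_of.get(d.tract, "unknown")

    pooled: dict[str, list[np.ndarray]] = {}
    for d in distributions:
        pooled.setdefault(key(d), []).append(d.replicates)
    groups = {k: np.concatenate(v) for k, v in pooled.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a head-to-head comparison")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs >= 2 replicate values")

    names = sorted(groups)
    arrays = [groups[k] for k in names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_anova = stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):        # degenerate (e.g. identical groups)
        f_stat, p_anova = 0.0, 1.0
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tval, pval = stats.ttest_ind(a, b, equal_var=False)
            if not np.isfinite(tval):
                tval, pval = 0.0, 1.0
            pairs.append((names[i], names[j], float(tval), float(pval)))
    posthoc = pd.DataFrame(pairs, columns=["group_a", "group_b", "t", "p"])
    posthoc["q"] = fdr_adjust(posthoc["p"].to_numpy())
    ranking = pd.DataFrame(
        {"group": names,
         "mean_delta_r2": [groups[k].mean() for k in names],
         "n_replicates": [len(groups[k]) for k in names]}
    ).sort_values("mean_delta_r2", ascending=False).reset_index(drop=True)
    return HeadToHeadReport(grouping=grouping, anova_f=float(f_stat),
                            anova_p=float(p_anova), posthoc=posthoc,
                            ranking=ranking)
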