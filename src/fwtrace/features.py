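"""Tract-mean feature extraction and the age-regressed outlier filter.

One imaging session contributes 240 features: the (weighted) mean of each
of the 5 scalar maps over each of the 48 tract masks.  Quality control
regresses every feature on baseline age and excludes a participant when any
feature's standardized residual exceeds a threshold (default 5 SD) in
absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import METRICS, TractAtlas, feature_name

__all__ = [
    "extract_features",
    "exclude_age_outliers",
    "OutlierStats",
]

KEY_COLUMNS = ("participant_id", "session")


def extract_features(maps: dict[str, np.ndarray], atlas: TractAtlas,
                     session_key: tuple[str, object]) -> pd.DataFrame:
    """Tract x metric mean features for one session's scalar maps.

    Parameters
    ----------
    maps
        Metric name -> 3-D scalar image; all metrics in
        :data:`fwtrace.atlas.METRICS` must be present on a common grid.
    atlas
        Atlas whose tracts carry binary or probabilistic weight masks.
    session_key
        ``(participant_id, session)`` identifying the row.

    Returns a single-row DataFrame with ``n_tracts * 5`` feature columns.
    Tract masks empty after NaN removal yield NaN with a warning.
    """
    missing = [m for m in METRICS if m not in maps]
    if missing:
        raise ValueError(f"missing metric maps: {missing}")
    shapes = {m: np.asarray(v).shape for m, v in maps.items()}
    ref_shape = next(iter(shapes.values()))
    if any(s != ref_shape for s in shapes.values()):
        raise ValueError(f"metric maps disagree on grid: {shapes}")

    row: dict[str, object] = {"participant_id": session_key[0],
                              "session": session_key[1]}
    for tract in atlas:
        if tract.mask is None:
            raise ValueError(f"tract {tract.name!r} has no mask "
                             "(atlas is in tabular mode)")
        w = np.asarray(tract.mask, dtype=float)
        if w.shape != ref_shape:
            raise ValueError(f"mask grid mismatch for tract {tract.name!r}")
        for metric in METRICS:
            vals = np.asarray(maps[metric], dtype=float)
            ok = (w > 0) & np.isfinite(vals)
            if not ok.any():
                warnings.warn(f"empty mask after NaN removal: "
                              f"{tract.name} / {metric}; feature set missing")
                row[feature_name(tract, metric)] = np.nan
                continue
            row[feature_name(tract, metric)] = float(
                np.average(vals[ok], weights=w[ok]))
    return pd.DataFrame([row])


@dataclass
class OutlierStats:
    """Frozen per-feature age-regression statistics (slope, intercept, SD).

    Passing these back into :func:`exclude_age_outliers` reuses the first
    pass's residual SDs, making the filter idempotent by construction.
    """

    params: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    threshold: float = 5.0


def exclude_age_outliers(features: pd.DataFrame,
                         age_col: str = "baseline_age",
                         id_col: str = "participant_id",
                         feature_cols: list[str] | None = None,
                         threshold: float = 5.0,
                         stats: OutlierStats | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, OutlierStats]:
    """Exclude participants with extreme age-regressed feature residuals.

    Each feature is regressed on ``age_col`` by simple linear regression
    (baseline rows; one row per participant expected).  A participant is
    excluded when *any* feature's |residual| / residual-SD exceeds
    ``threshold``.  Exclusion is participant-level: all of the
    participant's rows are dropped by callers holding the longitudinal
    table.

    Returns ``(filtered, report, stats)`` where ``report`` has one row per
    (participant, feature) violation with the residual in SD units.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c not in (age_col, id_col)
                        and pd.api.types.is_numeric_dtype(features[c])]
    n = len(features)
    if stats is None:
        if n < 10:
            raise ValueError("need >= 10 participants for a stable residual SD")
        stats = OutlierStats(threshold=threshold)
        age = features[age_col].to_numpy(float)
        for col in feature_cols:
            y = features[col].to_numpy(float)
            ok = np.isfinite(y) & np.isfinite(age)
            slope, intercept = np.polyfit(age[ok], y[ok], 1)
            resid = y[ok] - (intercept + slope * age[ok])
            sd = float(resid.std(ddof=2))
            stats.params[col] = (float(slope), float(intercept), sd)

    age = features[age_col].to_numpy(float)
    flagged: dict[object, list[tuple[str, float]]] = {}
    for col in feature_cols:
        if col not in stats.params:
            continue
        slope, intercept, sd = stats.params[col]
        if sd <= 0:
            continue
        y = features[col].to_numpy(float)
        z = (y - (intercept + slope * age)) / sd
        for i in np.nonzero(np.abs(z) > stats.threshold)[0]:
            flagged.setdefault(features[id_col].iloc[i], []).append(
                (col, float(z[i])))

    report = pd.DataFrame(
        [(pid, col, z) for pid, cols in flagged.items() for col, z in cols],
        columns=["participant_id", "feature", "residual_sd"])
    filtered = features[~features[id_col].isin(flagged)].reset_index(drop=True)
    return filtered, report, stats
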