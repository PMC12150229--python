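"""Synthetic multi-cohort longitudinal study generator.

Emulates the statistical structure of a pooled aging/AD neuroimaging study:
seven cohorts of unequal size with cohort-specific age, education, sex,
APOE e4 and diagnosis composition; a per-participant visit schedule with
1-13 years of follow-up; 240 tract x metric white-matter features carrying
imaging-batch location/scale shifts; cognitive composites (memory,
executive, language) generated from a linear mixed model in which the
annual slope depends on baseline white matter and, optionally, on white
matter x endophenotype interactions; and AD endophenotypes (hippocampal
volume, SPARE-AD, amyloid/tau positivity) correlated with the latent
white-matter burden.

Every generated quantity is driven by a single ``numpy`` Generator so that
identical (config, truth, seed) triples give identical tables, and the
generating parameters are returned alongside the table for recovery tests.

Generating model for each cognitive domain d of participant i at visit j::

    y_dij = mu_d + x_i' beta + beta_cross * w_i + b0_i
            + (b1_i + theta * w_i + theta_age * zage_i
               + sum_e phi_e * w_i * endo_ei) * t_ij + eps_dij

where w_i is the latent white-matter burden expressed (noise-free at
baseline) in the designated effect features, t_ij the interval in years
since baseline, and (b0_i, b1_i) independent Gaussian random effects.
Observed features are ``gamma_b + delta_b * true + noise`` per imaging
batch b.  Features are generated on a standardized (z) scale; physical
diffusivity units appear only in the DWI phantom path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .atlas import METRICS, atlas_registry, feature_names

__all__ = [
    "CohortConfig",
    "TruthParams",
    "SyntheticStudy",
    "DWIPhantom",
    "default_cohorts",
    "default_truth",
    "generate_study",
    "generate_dwi_phantom",
    "tensor_from_eigs",
    "tensor_from_fa_md",
    "sphere_directions",
    "WATER_DIFFUSIVITY",
]

#: isotropic diffusivity of free water at body temperature, mm^2/s
WATER_DIFFUSIVITY = 3.0e-3

DIAGNOSES = ("CU", "MCI", "AD")
DOMAINS = ("memory", "executive", "language")
ENDOPHENOTYPES = ("hippocampal_volume", "spare_ad", "amyloid_positive", "tau_positive")

_RACE_LEVELS = ("NH White", "NH Black", "Hispanic", "Other")
_RACE_PROBS = (0.80, 0.12, 0.05, 0.03)


@dataclass
class CohortConfig:
    """Design of one cohort: size, age structure, schedule and composition."""

    name: str
    n_participants: int
    age_mean: float
    age_sd: float
    visit_count_mean: float          # mean number of visits incl. baseline
    visit_interval_mean: float       # mean gap between visits, years
    diagnosis_mix: dict[str, float]  # proportions over CU / MCI / AD
    apoe4_rate: float
    female_rate: float = 0.55
    education_mean: float = 16.0
    education_sd: float = 3.0
    batch_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"{self.name}: n_participants must be >= 1")
        if self.visit_interval_mean <= 0:
            raise ValueError(f"{self.name}: visit_interval_mean must be > 0")
        total = sum(self.diagnosis_mix.get(d, 0.0) for d in DIAGNOSES)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{self.name}: diagnosis_mix must sum to 1 (got {total:.4f})")
        if not self.batch_ids:
            self.batch_ids = (f"batch_{self.name}",)


def default_cohorts() -> list[CohortConfig]:
    """Seven cohorts mirroring the pooled study's published composition."""
    rows = [
        # name, n, age_mu, age_sd, visits, gap, (CU, MCI, AD), apoe4, fem, edu_mu, edu_sd
        ("ADNI",    830, 74.75,  7.50, 2.17, 2.3, (0.474, 0.392, 0.134), 0.357, 0.498, 16.33, 2.59),
        ("BLSA",    757, 70.45, 10.28, 2.56, 2.6, (0.989, 0.008, 0.003), 0.255, 0.552, 17.00, 2.39),
        ("BIOCARD", 127, 71.81,  7.40, 1.17, 2.0, (0.803, 0.173, 0.024), 0.370, 0.622, 17.44, 2.19),
        ("NACC",    974, 74.95,  8.11, 1.34, 1.9, (0.565, 0.283, 0.152), 0.395, 0.578, 14.51, 3.96),
        ("ROSMAPMARS", 1160, 79.48, 7.32, 2.21, 3.2, (0.807, 0.180, 0.013), 0.190, 0.772, 15.84, 3.31),
        ("VMAP",    326, 73.32,  7.23, 3.16, 1.4, (0.595, 0.402, 0.003), 0.353, 0.414, 15.83, 2.67),
        ("WRAP",    293, 62.01,  6.20, 1.46, 3.2, (0.987, 0.010, 0.003), 0.307, 0.662, 16.62, 2.78),
    ]
    cohorts = []
    for name, n, amu, asd, vis, gap, mix, apoe4, fem, emu, esd in rows:
        total = sum(mix)
        cohorts.append(CohortConfig(
            name=name, n_participants=n, age_mean=amu, age_sd=asd,
            visit_count_mean=vis, visit_interval_mean=gap,
            diagnosis_mix={d: m / total for d, m in zip(DIAGNOSES, mix)},
            apoe4_rate=apoe4, female_rate=fem,
            education_mean=emu, education_sd=esd,
        ))
    return cohorts


@dataclass
class TruthParams:
    """Generating parameters; the recoverable ground truth of a simulation."""

    # white-matter effects (standardized scale)
    beta_wm_cross: float = -0.30     # baseline WM -> baseline cognition
    theta_wm_slope: float = -0.15    # baseline WM -> annual cognitive slope
    effect_features: tuple[str, ...] = ("fornix_FW",)
    #: per-domain multipliers on the WM effects (memory-dominant pattern)
    domain_gain: dict[str, float] = field(
        default_factory=lambda: {"memory": 1.0, "executive": 0.6, "language": 0.5})
    # WM x endophenotype (x interval) interactions; keyed by endophenotype
    phi_endo: dict[str, float] = field(default_factory=dict)
    endo_wm_corr: float = 0.4

    # covariate effects on cognition (per SD / per level)
    beta_age: float = -0.25
    beta_education: float = 0.10
    beta_female: float = 0.05
    beta_mci: float = -0.90
    beta_ad: float = -1.80
    beta_apoe4: float = -0.05
    theta_age_slope: float = -0.03   # baseline age x interval

    # random effects and noise
    sigma_subject_intercept: float = 0.50
    sigma_subject_slope: float = 0.08
    sigma_resid: float = 0.35

    # feature model
    feature_age_slope: float = 0.35      # per SD of age, sign flipped for FAt
    feature_subject_sd: float = 0.70     # subject-level feature intercept
    feature_noise_sd: float = 0.714      # visit-level feature noise
    # imaging-batch effects: additive gamma_b plus scale delta_b on the
    # visit-level noise (location-scale convention of the harmonizer)
    gamma_batch: dict[str, float] | None = None
    delta_batch: dict[str, float] | None = None

    # endophenotype marginals
    amyloid_rate: float = 0.33
    tau_rate: float = 0.22
    apoe2_rate: float = 0.12

    # optional monotone dropout hazard per visit (default off)
    dropout_hazard: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_batch is not None and any(d <= 0 for d in self.delta_batch.values()):
            raise ValueError("delta_batch scale factors must be > 0")
        for name, val in (("sigma_subject_intercept", self.sigma_subject_intercept),
                          ("sigma_subject_slope", self.sigma_subject_slope),
                          ("sigma_resid", self.sigma_resid)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


#: default batch location/scale shifts, cycled over the batch labels in use
_DEFAULT_GAMMA_CYCLE = (0.00, 0.12, -0.15, 0.20, -0.06, 0.10, -0.10)
_DEFAULT_DELTA_CYCLE = (1.00, 1.15, 0.85, 1.20, 0.95, 1.10, 0.90)


def default_truth(**overrides) -> TruthParams:
    return TruthParams(**overrides)


@dataclass
class SyntheticStudy:
    """A generated study: long table + the truth that produced it."""

    table: pd.DataFrame
    truth: TruthParams
    latent: pd.DataFrame         # per-participant w, b0, b1
    batch_gamma: dict[str, float]
    batch_delta: dict[str, float]


def _visit_times(rng: np.random.Generator, cfg: CohortConfig,
                 truth: TruthParams, max_followup: float = 13.0) -> list[np.ndarray]:
    """Per-participant visit times in years since baseline (first = 0)."""
    n = cfg.n_participants
    extra = rng.poisson(max(cfg.visit_count_mean - 1.0, 0.0), size=n)
    times = []
    for k in extra:
        gaps = cfg.visit_interval_mean * rng.uniform(0.6, 1.4, size=int(k))
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        t = t[t <= max_followup]
        if truth.dropout_hazard > 0 and len(t) > 1:
            drop = rng.random(len(t) - 1) < truth.dropout_hazard
            if drop.any():
                t = t[: 1 + int(np.argmax(drop))]
        times.append(t)
    return times


def generate_study(configs: list[CohortConfig] | None = None,
                   truth: TruthParams | None = None,
                   seed: int = 0,
                   features: list[str] | None = None) -> SyntheticStudy:
    """Generate a multi-cohort longitudinal study table.

    Parameters
    ----------
    configs
        Cohort designs; defaults to :func:`default_cohorts`.
    truth
        Generating parameters; defaults to :func:`default_truth`.
    seed
        Seed for the single Generator driving all randomness.
    features
        Feature columns to generate (default: the full 240-column
        tract x metric set).  Effect features are always included.
    """
    if configs is None:
        configs = default_cohorts()
    if not configs:
        raise ValueError("configs must be non-empty")
    if truth is None:
        truth = default_truth()
    if features is None:
        features = feature_names(atlas_registry(), METRICS)
    features = list(dict.fromkeys(list(features) + list(truth.effect_features)))

    rng = np.random.default_rng(seed)

    # resolve batch effect maps over all batch labels in play
    all_batches: list[str] = []
    for cfg in configs:
        for b in cfg.batch_ids:
            if b not in all_batches:
                all_batches.append(b)
    gamma = dict(truth.gamma_batch) if truth.gamma_batch is not None else {
        b: _DEFAULT_GAMMA_CYCLE[i % len(_DEFAULT_GAMMA_CYCLE)]
        for i, b in enumerate(all_batches)}
    delta = dict(truth.delta_batch) if truth.delta_batch is not None else {
        b: _DEFAULT_DELTA_CYCLE[i % len(_DEFAULT_DELTA_CYCLE)]
        for i, b in enumerate(all_batches)}
    for b in all_batches:
        gamma.setdefault(b, 0.0)
        delta.setdefault(b, 1.0)
        if delta[b] <= 0:
            raise ValueError("delta_batch scale factors must be > 0")

    frames = []
    latents = []
    for cfg in configs:
        n = cfg.n_participants
        pid = np.array([f"{cfg.name}_{i:05d}" for i in range(n)])
        age0 = rng.normal(cfg.age_mean, cfg.age_sd, n)
        female = rng.random(n) < cfg.female_rate
        edu = np.clip(rng.normal(cfg.education_mean, cfg.education_sd, n), 6.0, 22.0)
        race = rng.choice(_RACE_LEVELS, size=n, p=_RACE_PROBS)
        apoe4 = rng.random(n) < cfg.apoe4_rate
        apoe2 = rng.random(n) < truth.apoe2_rate
        probs = np.array([cfg.diagnosis_mix[d] for d in DIAGNOSES])
        dx = rng.choice(DIAGNOSES, size=n, p=probs / probs.sum())
        batch = rng.choice(np.array(cfg.batch_ids), size=n)

        # latent white-matter burden and subject random effects
        w = rng.standard_normal(n)
        b0 = truth.sigma_subject_intercept * rng.standard_normal(n)
        b1 = truth.sigma_subject_slope * rng.standard_normal(n)

        # endophenotypes correlated with w
        rho = truth.endo_wm_corr
        res = math.sqrt(max(1.0 - rho ** 2, 0.0))
        hippo = -rho * w + res * rng.standard_normal(n)
        spare = rho * w + res * rng.standard_normal(n)
        amy_lat = 0.3 * w + math.sqrt(1 - 0.09) * rng.standard_normal(n)
        tau_lat = 0.3 * w + math.sqrt(1 - 0.09) * rng.standard_normal(n)
        amy = amy_lat > norm.ppf(1.0 - truth.amyloid_rate)
        tau = tau_lat > norm.ppf(1.0 - truth.tau_rate)

        times = _visit_times(rng, cfg, truth)
        n_vis = np.array([len(t) for t in times])
        idx = np.repeat(np.arange(n), n_vis)
        t = np.concatenate(times)
        visit_index = np.concatenate([np.arange(k) for k in n_vis])

        conv = (dx != "CU")
        multi = n_vis > 1
        conv = conv | ((~conv) & multi & (rng.random(n) < 0.10))

        zage0 = (age0 - 74.3) / 9.2
        zedu = (edu - 15.9) / 3.2

        # cognitive composites from the mixed model
        slope_core = b1 + truth.theta_age_slope * zage0
        for endo_name, phi in truth.phi_endo.items():
            endo_vals = {"hippocampal_volume": hippo, "spare_ad": spare,
                         "amyloid_positive": amy.astype(float),
                         "tau_positive": tau.astype(float)}[endo_name]
            slope_core = slope_core + phi * w * endo_vals
        level_core = (truth.beta_age * zage0 + truth.beta_education * zedu
                      + truth.beta_female * female
                      + truth.beta_mci * (dx == "MCI") + truth.beta_ad * (dx == "AD")
                      + truth.beta_apoe4 * apoe4 + b0)
        base_mu = {"memory": 0.47, "executive": 0.40, "language": 0.51}
        cog = {}
        for d in DOMAINS:
            g = truth.domain_gain.get(d, 1.0)
            mean_ij = (base_mu[d] + level_core[idx]
                       + g * truth.beta_wm_cross * w[idx]
                       + (slope_core[idx] + g * truth.theta_wm_slope * w[idx]) * t)
            cog[d] = mean_ij + truth.sigma_resid * rng.standard_normal(len(t))

        data = {
            "participant_id": pid[idx],
            "cohort": cfg.name,
            "batch": batch[idx],
            "visit_index": visit_index,
            "baseline_age": age0[idx],
            "age_at_visit": age0[idx] + t,
            "interval": t,
            "sex": np.where(female[idx], "female", "male"),
            "education": edu[idx],
            "race_ethnicity": race[idx],
            "apoe4": apoe4[idx].astype(int),
            "apoe2": apoe2[idx].astype(int),
            "baseline_diagnosis": dx[idx],
            "converter": conv[idx].astype(int),
            "memory": cog["memory"],
            "executive": cog["executive"],
            "language": cog["language"],
            "hippocampal_volume": hippo[idx],
            "spare_ad": spare[idx],
            "amyloid_positive": amy[idx].astype(int),
            "tau_positive": tau[idx].astype(int),
        }

        zage_ij = (age0[idx] + t - 74.3) / 9.2
        g_row = np.array([gamma[b] for b in batch])[idx]
        d_row = np.array([delta[b] for b in batch])[idx]
        # batch location shift gamma_b plus scale delta_b acting on the
        # visit-level measurement noise (the location-scale convention the
        # harmonization model assumes); biological structure is unscaled
        effect = set(truth.effect_features)
        for feat in features:
            sign = -1.0 if feat.endswith("_FAt") else 1.0
            age_term = sign * truth.feature_age_slope * zage_ij
            if feat in effect:
                data[feat] = g_row + w[idx] + age_term
            else:
                u = truth.feature_subject_sd * rng.standard_normal(n)
                e = truth.feature_noise_sd * rng.standard_normal(len(t))
                data[feat] = g_row + u[idx] + age_term + d_row * e
        frames.append(pd.DataFrame(data))
        latents.append(pd.DataFrame({"participant_id": pid, "w": w,
                                     "b0": b0, "b1": b1, "cohort": cfg.name}))

    table = pd.concat(frames, ignore_index=True)
    latent = pd.concat(latents, ignore_index=True)
    return SyntheticStudy(table=table, truth=truth, latent=latent,
                          batch_gamma=gamma, batch_delta=delta)


# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------

def sphere_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def tensor_from_eigs(eigenvalues, principal_direction=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Axially oriented symmetric tensor with the given eigenvalues.

    The first eigenvalue is aligned with ``principal_direction``; the two
    others span its orthogonal complement.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,) or np.any(lam < 0):
        raise ValueError("eigenvalues must be 3 non-negative values")
    e1 = np.asarray(principal_direction, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(lam) @ R.T


def tensor_from_fa_md(fa: float, md: float,
                      principal_direction=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Prolate tensor with the requested FA and mean diffusivity.

    For an axially symmetric tensor (l1, l2=l3) with trace 3*md,
    l1 = md(1+2a), l2 = l3 = md(1-a) with a = FA / sqrt(3 - 2 FA^2).
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must be in [0, 1)")
    a = fa / math.sqrt(3.0 - 2.0 * fa ** 2)
    lam = np.array([md * (1 + 2 * a), md * (1 - a), md * (1 - a)])
    return tensor_from_eigs(lam, principal_direction)


@dataclass
class DWIPhantom:
    """Voxelwise single-shell signals with per-voxel ground truth."""

    signals: np.ndarray      # (n_voxels, n_volumes)
    bvals: np.ndarray        # (n_volumes,)
    bvecs: np.ndarray        # (n_volumes, 3)
    f_true: np.ndarray       # (n_voxels,)
    D_true: np.ndarray       # (n_voxels, 3, 3)
    s0: float


def generate_dwi_phantom(n_voxels: int,
                         f_values,
                         tensor_spec,
                         bval: float = 1000.0,
                         n_directions: int = 32,
                         snr: float | None = None,
                         seed: int = 0,
                         s0: float = 100.0,
                         n_b0: int = 1,
                         d_water: float = WATER_DIFFUSIVITY) -> DWIPhantom:
    """Forward-simulate bi-tensor single-shell signals.

    ``S(g, b) = s0 * [(1-f) exp(-b g'Dg) + f exp(-b d_water)]`` per voxel,
    with optional Rician noise at the given SNR (defined on the b=0 signal).

    ``tensor_spec`` is either one 3x3 tensor used everywhere or an
    (n_voxels, 3, 3) stack.
    """
    f = np.broadcast_to(np.asarray(f_values, dtype=float), (n_voxels,)).copy()
    if np.any((f < 0) | (f > 1)):
        raise ValueError("free-water fractions must lie in [0, 1]")
    D = np.asarray(tensor_spec, dtype=float)
    if D.shape == (3, 3):
        D = np.broadcast_to(D, (n_voxels, 3, 3)).copy()
    if D.shape != (n_voxels, 3, 3):
        raise ValueError("tensor_spec must be 3x3 or (n_voxels, 3, 3)")
    if bval <= 0:
        raise ValueError("bval must be > 0")

    dirs = sphere_directions(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])

    # g' D g for every (voxel, direction)
    adc = np.einsum("gi,vij,gj->vg", dirs, D, dirs)
    atten = (1.0 - f[:, None]) * np.exp(-bval * adc) + f[:, None] * math.exp(-bval * d_water)
    signals = np.concatenate(
        [np.full((n_voxels, n_b0), s0), s0 * atten], axis=1)

    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, signals.shape)
        n2 = rng.normal(0.0, sigma, signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2 ** 2)

    return DWIPhantom(signals=signals, bvals=bvals, bvecs=bvecs,
                      f_true=f, D_true=D, s0=s0)
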