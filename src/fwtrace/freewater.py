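"""Single-shell bi-tensor free-water fit and FW-corrected scalar metrics.

The signal in a voxel is modelled as a mixture of a tissue compartment with
symmetric positive-definite diffusion tensor ``D`` and an isotropic
free-water compartment with fixed diffusivity ``d_w = 3.0e-3 mm^2/s``::

    S(g, b) = S0 * [(1 - f) exp(-b g'Dg) + f exp(-b d_w)]

With a single non-zero shell this fit is ill-posed without constraints, so
the tissue eigenvalues are box-constrained to [1e-4, 2.9e-3] mm^2/s (mapped
into the box by a sigmoid so the constraint holds throughout optimization),
``f`` is optimized on the logit scale and the tensor orientation through
Euler angles.  A vanishingly small ridge penalty on ``f`` selects the
smallest-FW solution when the data are direction-independent and the
decomposition is degenerate (isotropic tissue).  The fit is voxelwise
(no spatial regularization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .synthetic import WATER_DIFFUSIVITY

__all__ = [
    "GradientTable",
    "FitOptions",
    "FWFit",
    "ScalarSet",
    "fit_bitensor",
    "tensor_scalars",
    "map_volume",
]

_B0_THRESHOLD = 50.0       # s/mm^2; volumes below count as b=0
_EIG_MIN, _EIG_MAX = 1.0e-4, 2.9e-3   # tissue eigenvalue plausibility box
_LOGIT_BOUND = 9.3         # f in [~9e-5, 1-9e-5]


@dataclass
class GradientTable:
    """Acquisition table: b-value (s/mm^2) and unit b-vector per volume."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] != self.bvecs.shape[1]:
            self.bvecs = self.bvecs.T
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        if not np.any(self.b0_mask):
            raise ValueError("gradient table needs at least one b=0 volume")
        norms = np.linalg.norm(self.bvecs[~self.b0_mask], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero b-vectors must be unit norm (tol 1e-6)")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < _B0_THRESHOLD

    @classmethod
    def from_files(cls, bval_path, bvec_path) -> "GradientTable":
        """Read FSL-style bval/bvec text files."""
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals, bvecs)


@dataclass
class FitOptions:
    d_water: float = WATER_DIFFUSIVITY
    max_iter: int = 500
    ftol: float = 1e-10
    multi_start: bool = True


@dataclass
class FWFit:
    f: float
    D_tissue: np.ndarray     # 3x3 symmetric PSD, mm^2/s
    s0: float
    converged: bool
    n_iter: int
    objective: float = float("nan")


@dataclass
class ScalarSet:
    """FW plus the FW-corrected tensor scalars of one voxel."""

    FW: float
    FAt: float
    MDt: float
    AxDt: float
    RDt: float

    def as_dict(self) -> dict[str, float]:
        return {"FW": self.FW, "FAt": self.FAt, "MDt": self.MDt,
                "AxDt": self.AxDt, "RDt": self.RDt}


def _design_matrix(bvecs: np.ndarray) -> np.ndarray:
    """Rows map the 6 unique tensor elements to g'Dg (xx, yy, zz, xy, xz, yz)."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack([gx * gx, gy * gy, gz * gz,
                            2 * gx * gy, 2 * gx * gz, 2 * gy * gz])


def _tensor_from_vec(d6: np.ndarray) -> np.ndarray:
    xx, yy, zz, xy, xz, yz = d6
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def _loglinear_dti(atten: np.ndarray, b: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Ordinary log-linear DTI fit of an attenuation profile -> 3x3 tensor."""
    y = -np.log(np.clip(atten, 1e-8, None)) / b
    X = _design_matrix(bvecs)
    d6, *_ = np.linalg.lstsq(X, y, rcond=None)
    return _tensor_from_vec(d6)


def _clamp_spd(D: np.ndarray) -> np.ndarray:
    """Project onto the symmetric box-constrained eigenvalue set."""
    Ds = 0.5 * (D + D.T)
    lam, V = np.linalg.eigh(Ds)
    lam = np.clip(lam, _EIG_MIN, _EIG_MAX)
    return V @ np.diag(lam) @ V.T


_U_BOUND = 12.0  # sigmoid eigenvalue parameter bound


def _chol_params(D: np.ndarray) -> np.ndarray:
    """Lower-Cholesky parameters of D scaled to units of 1e-3 mm^2/s."""
    Ds = _clamp_spd(D) * 1e3
    L = np.linalg.cholesky(Ds + 1e-9 * np.eye(3))
    return np.array([L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2]])


def _tensor_from_chol(p6: np.ndarray) -> np.ndarray:
    L = np.array([[p6[0], 0.0, 0.0], [p6[1], p6[2], 0.0],
                  [p6[3], p6[4], p6[5]]])
    return (L @ L.T) * 1e-3


def _eig_to_u(lam: np.ndarray) -> np.ndarray:
    """Inverse of the sigmoid map from R to the eigenvalue box."""
    frac = (np.clip(lam, _EIG_MIN * 1.001, _EIG_MAX * 0.999) - _EIG_MIN) \
        / (_EIG_MAX - _EIG_MIN)
    return np.log(frac / (1.0 - frac))


def _boxed_params_from_tensor(D: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eigh(0.5 * (D + D.T))
    if np.linalg.det(V) < 0:
        V[:, 0] = -V[:, 0]
    rotvec = Rotation.from_matrix(V).as_rotvec()
    return np.concatenate([_eig_to_u(lam), rotvec])


def _tensor_from_boxed(p6: np.ndarray) -> np.ndarray:
    """(u1..u3, rotation vector) -> symmetric tensor, eigenvalues in-box."""
    lam = _EIG_MIN + (_EIG_MAX - _EIG_MIN) / (1.0 + np.exp(-np.clip(p6[:3], -40, 40)))
    V = Rotation.from_rotvec(p6[3:]).as_matrix()
    return (V * lam) @ V.T


def fit_bitensor(signals, gtab: GradientTable,
                 options: FitOptions | None = None) -> FWFit:
    """Fit the bi-tensor free-water model to one voxel's signals.

    Least squares over (logit f, chol D) on the normalized attenuations,
    with f initialized from the mean-ADC heuristic
    ``f0 = log(S0 / mean(S_b)) / (b * d_w)`` and D from a log-linear DTI
    fit of the f0-corrected attenuations.
    """
    opts = options or FitOptions()
    s = np.asarray(signals, dtype=float).ravel()
    if s.shape != gtab.bvals.shape:
        raise ValueError("signals and gradient table lengths differ")
    if not np.all(np.isfinite(s)):
        raise ValueError("signals must be finite")
    if np.any(s <= 0):
        raise ValueError("signals must be positive")
    b0 = gtab.b0_mask
    n_dwi = int((~b0).sum())
    if n_dwi < 6 or len(s) < 7:
        raise ValueError("need >= 6 diffusion-weighted volumes and >= 1 b0")

    s0 = float(s[b0].mean())
    b = gtab.bvals[~b0]
    g = gtab.bvecs[~b0]
    atten = np.clip(s[~b0] / s0, 1e-8, None)
    bm = float(b.mean())
    aw = np.exp(-b * opts.d_water)          # free-water attenuation per volume

    # tie-break residual: on degenerate (direction-independent) ridges the
    # smallest-FW decomposition is preferred; negligible elsewhere
    _EPS_F = 1e-4

    def _residuals(p, tensor_of):
        f = 1.0 / (1.0 + np.exp(-p[0]))
        D = tensor_of(p[1:])
        adc = np.einsum("gi,ij,gj->g", g, D, g)
        model = (1.0 - f) * np.exp(-b * adc) + f * aw
        return np.concatenate([model - atten, [_EPS_F * f]])

    # heuristic initializations
    md_est = math.log(max(s0 / max(s[~b0].mean(), 1e-8), 1.0 + 1e-9)) / bm
    f0 = float(np.clip(md_est / opts.d_water, 1e-3, 0.95))
    starts = [f0]
    if opts.multi_start:
        starts += [max(f0 - 0.3, 1e-3), min(f0 + 0.3, 0.97)]

    ls_opts = dict(method="trf", xtol=1e-12, ftol=opts.ftol * 1e-4,
                   gtol=1e-14, max_nfev=opts.max_iter)

    # stage 1: unconstrained Cholesky parameterization (exact and fast when
    # the tissue tensor is identifiable and inside the plausibility box)
    fb = (-_LOGIT_BOUND, _LOGIT_BOUND)
    lower1 = np.array([fb[0]] + [-3.0] * 6)
    upper1 = np.array([fb[1]] + [3.0] * 6)
    best = None
    for fs in starts:
        at = np.clip((atten - fs * aw) / max(1.0 - fs, 1e-3), 1e-6, None)
        D_init = _loglinear_dti(at, b, g)
        p0 = np.concatenate([[math.log(fs / (1.0 - fs))], _chol_params(D_init)])
        p0 = np.clip(p0, lower1 + 1e-9, upper1 - 1e-9)
        res = least_squares(lambda p: _residuals(p, _tensor_from_chol), p0,
                            bounds=(lower1, upper1), **ls_opts)
        if best is None or res.cost < best.cost:
            best = res
        f_cur = 1.0 / (1.0 + np.exp(-best.x[0]))
        data_cost = 2.0 * best.cost - (_EPS_F * f_cur) ** 2
        if data_cost < 1e-13:       # perfect fit, no further starts needed
            break
    f_hat = float(1.0 / (1.0 + np.exp(-best.x[0])))
    D_raw = _tensor_from_chol(best.x[1:])
    lam = np.linalg.eigvalsh(D_raw)

    # stage 2: if the unconstrained optimum leaves the eigenvalue box (e.g.
    # the pure-water limit, where tissue D -> d_w is indistinguishable from
    # free water), refit with eigenvalues sigmoid-mapped into the box
    if lam.min() < _EIG_MIN - 1e-9 or lam.max() > _EIG_MAX + 1e-9:
        lower2 = np.array([fb[0]] + [-_U_BOUND] * 3 + [-10.0] * 3)
        upper2 = -lower2
        best2 = None
        for fs in (f_hat, 0.9, 0.1):
            fs = float(np.clip(fs, 1e-3, 1 - 1e-3))
            p0 = np.concatenate([[math.log(fs / (1.0 - fs))],
                                 _boxed_params_from_tensor(D_raw)])
            p0 = np.clip(p0, lower2 + 1e-9, upper2 - 1e-9)
            res = least_squares(lambda p: _residuals(p, _tensor_from_boxed),
                                p0, bounds=(lower2, upper2), **ls_opts)
            if best2 is None or res.cost < best2.cost:
                best2 = res
        best = best2
        f_hat = float(1.0 / (1.0 + np.exp(-best.x[0])))
        D_raw = _tensor_from_boxed(best.x[1:])

    D_hat = _clamp_spd(D_raw)
    return FWFit(f=f_hat, D_tissue=D_hat, s0=s0,
                 converged=bool(best.status > 0), n_iter=int(best.nfev),
                 objective=float(2.0 * best.cost))


def tensor_scalars(fit: FWFit) -> ScalarSet:
    """FW-corrected DTI scalars from a fitted voxel.

    With eigenvalues l1 >= l2 >= l3 of the tissue tensor:
    MDt = mean(l), FAt = sqrt(3/2 * sum((l - MDt)^2) / sum(l^2)),
    AxDt = l1, RDt = (l2 + l3) / 2; FW = f.
    """
    D = np.asarray(fit.D_tissue, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("D_tissue must be 3x3")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("D_tissue not symmetric within 1e-9")
    lam = np.sort(np.linalg.eigvalsh(D))[::-1]
    if lam[-1] < -1e-12:
        raise ValueError("D_tissue must be positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    md = float(lam.mean())
    denom = float(np.sum(lam ** 2))
    fa = 0.0 if denom == 0.0 else float(
        math.sqrt(1.5 * float(np.sum((lam - md) ** 2)) / denom))
    return ScalarSet(FW=float(fit.f), FAt=min(fa, 1.0), MDt=md,
                     AxDt=float(lam[0]), RDt=float(0.5 * (lam[1] + lam[2])))


def map_volume(dwi: np.ndarray, gtab: GradientTable, mask: np.ndarray,
               options: FitOptions | None = None) -> dict[str, np.ndarray]:
    """Voxelwise bi-tensor fit over a 4-D volume.

    Returns the five scalar maps (FW, FAt, MDt, AxDt, RDt) with NaN outside
    the mask.  Per-voxel values are identical to calling
    :func:`fit_bitensor` + :func:`tensor_scalars` on that voxel.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4-D (x, y, z, volumes)")
    if dwi.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: dwi {dwi.shape[:3]} vs mask {mask.shape}")
    if dwi.shape[3] != len(gtab.bvals):
        raise ValueError("dwi volume count does not match gradient table")
    if not mask.any():
        raise ValueError("mask is empty")

    maps = {name: np.full(mask.shape, np.nan) for name in
            ("FW", "FAt", "MDt", "AxDt", "RDt")}
    for ijk in zip(*np.nonzero(mask)):
        scal = tensor_scalars(fit_bitensor(dwi[ijk], gtab, options))
        for name, val in scal.as_dict().items():
            maps[name][ijk] = val
    return maps
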