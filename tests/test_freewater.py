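"""Bi-tensor fit: recovery, limits, scalar formulas, volume wrapper."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwtrace.freewater import (FitOptions, FWFit, GradientTable, fit_bitensor,
                               map_volume, tensor_scalars)
from fwtrace.synthetic import (generate_dwi_phantom, tensor_from_eigs,
                               tensor_from_fa_md)


def _gtab(ph):
    return GradientTable(ph.bvals, ph.bvecs)


class TestGradientTable:
    def test_requires_b0(self):
        with pytest.raises(ValueError, match="b=0"):
            GradientTable(np.full(10, 1000.0), np.eye(3)[np.zeros(10, int)])

    def test_requires_unit_bvecs(self):
        bvals = np.array([0.0, 1000.0])
        bvecs = np.array([[0, 0, 0], [0.5, 0, 0]])
        with pytest.raises(ValueError, match="unit norm"):
            GradientTable(bvals, bvecs)


class TestFitBitensor:
    def test_noiseless_recovery(self):
        """f = 0.3 with a (1.7, .2, .2)e-3 tensor: f within 0.01 and
        eigenvalues within 5%."""
        lam_true = np.array([1.7e-3, 0.2e-3, 0.2e-3])
        ph = generate_dwi_phantom(1, 0.3, tensor_from_eigs(lam_true),
                                  bval=1000, n_directions=32)
        fit = fit_bitensor(ph.signals[0], _gtab(ph))
        assert abs(fit.f - 0.3) <= 0.01
        lam = np.sort(np.linalg.eigvalsh(fit.D_tissue))[::-1]
        assert np.all(np.abs(lam - lam_true) / lam_true <= 0.05)

    def test_isotropic_no_water(self):
        """Degenerate isotropic voxel resolves to the minimal-FW solution."""
        ph = generate_dwi_phantom(1, 0.0, tensor_from_eigs([0.7e-3] * 3),
                                  bval=1000, n_directions=32)
        fit = fit_bitensor(ph.signals[0], _gtab(ph))
        assert fit.f <= 0.02
        assert tensor_scalars(fit).MDt == pytest.approx(0.7e-3, rel=0.02)

    def test_pure_water_limit(self):
        ph = generate_dwi_phantom(1, 1.0, tensor_from_eigs([1.7e-3, 2e-4, 2e-4]),
                                  bval=1000, n_directions=32)
        fit = fit_bitensor(ph.signals[0], _gtab(ph))
        assert fit.f >= 0.98

    def test_monotone_in_true_f(self):
        """Fitted f never decreases as true f increases (fixed tissue)."""
        D = tensor_from_eigs([1.7e-3, 0.2e-3, 0.2e-3])
        fits = []
        for f in np.arange(0.0, 0.91, 0.1):
            ph = generate_dwi_phantom(1, f, D, bval=1000, n_directions=32)
            fits.append(fit_bitensor(ph.signals[0], _gtab(ph)).f)
        assert np.all(np.diff(fits) >= -1e-6)

    def test_noise_robustness_snr30(self):
        """Rician noise at SNR 30 on a 64-direction shell: |mean bias of
        f| <= 0.05 over a mixed-anisotropy grid (seeded).  The voxelwise
        single-shell fit is weakly identified under noise, so the bias is
        assessed over a representative FA range, not a single tensor."""
        fas = np.tile(np.arange(0.1, 0.81, 0.1), 8)[:60]
        D = np.stack([tensor_from_fa_md(fa, 0.7e-3) for fa in fas])
        ph = generate_dwi_phantom(60, 0.3, D, bval=1000, n_directions=64,
                                  snr=30, seed=5)
        gt = _gtab(ph)
        f_hat = np.array([fit_bitensor(s, gt).f for s in ph.signals])
        assert abs(f_hat.mean() - 0.3) <= 0.05

    def test_input_validation(self):
        ph = generate_dwi_phantom(1, 0.3, tensor_from_fa_md(0.5, 7e-4),
                                  n_directions=32)
        gt = _gtab(ph)
        bad = ph.signals[0].copy()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_bitensor(bad, gt)
        ph2 = generate_dwi_phantom(1, 0.3, tensor_from_fa_md(0.5, 7e-4),
                                   n_directions=5)
        with pytest.raises(ValueError, match=">= 6"):
            fit_bitensor(ph2.signals[0], _gtab(ph2))


class TestTensorScalars:
    def test_prolate_fa(self):
        """FA of (1.7, .2, .2)e-3 equals 0.8704 to 4 decimals."""
        fit = FWFit(f=0.1, D_tissue=tensor_from_eigs([1.7e-3, 2e-4, 2e-4]),
                    s0=1.0, converged=True, n_iter=0)
        sc = tensor_scalars(fit)
        assert sc.FAt == pytest.approx(0.8704, abs=1e-4)
        assert sc.MDt == pytest.approx(0.7e-3, rel=1e-9)
        assert sc.AxDt == pytest.approx(1.7e-3)
        assert sc.RDt == pytest.approx(2e-4)
        assert sc.FW == pytest.approx(0.1)

    def test_isotropy_and_degenerate_limits(self):
        iso = FWFit(0.0, tensor_from_eigs([0.7e-3] * 3), 1.0, True, 0)
        sc = tensor_scalars(iso)
        assert sc.FAt == 0.0
        assert sc.AxDt == sc.RDt == pytest.approx(0.7e-3)
        stick = FWFit(0.0, np.diag([1e-3, 0.0, 0.0]), 1.0, True, 0)
        assert tensor_scalars(stick).FAt == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           fa=st.floats(min_value=0.0, max_value=0.95))
    def test_fa_scale_invariance(self, c, fa):
        """FA is invariant under D -> cD for any c > 0."""
        D = tensor_from_fa_md(fa, 0.7e-3)
        f1 = tensor_scalars(FWFit(0.0, D, 1.0, True, 0)).FAt
        f2 = tensor_scalars(FWFit(0.0, c * D, 1.0, True, 0)).FAt
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_rejects_asymmetric(self):
        D = tensor_from_eigs([1e-3, 2e-4, 2e-4])
        D[0, 1] += 1e-6
        with pytest.raises(ValueError, match="symmetric"):
            tensor_scalars(FWFit(0.0, D, 1.0, True, 0))


class TestMapVolume:
    def test_constant_phantom_and_mask(self):
        """Homogeneous 3x3x3 volume: constant maps equal the single-voxel
        fit; an excluded voxel is NaN everywhere."""
        D = tensor_from_eigs([1.7e-3, 2e-4, 2e-4])
        ph = generate_dwi_phantom(1, 0.3, D, bval=1000, n_directions=16)
        gt = _gtab(ph)
        vol = np.tile(ph.signals[0], (3, 3, 3, 1))
        mask = np.ones((3, 3, 3), bool)
        mask[1, 1, 1] = False
        maps = map_volume(vol, gt, mask)
        single = tensor_scalars(fit_bitensor(ph.signals[0], gt)).as_dict()
        for name, m in maps.items():
            assert np.isnan(m[1, 1, 1])
            vals = m[mask]
            assert np.allclose(vals, single[name])

    def test_voxelwise_equality_with_loop_oracle(self):
        """Mixed-truth 4x4x1 grid: map output equals per-voxel fits."""
        fs = np.linspace(0.0, 0.6, 16)
        D = np.stack([tensor_from_fa_md(0.3 + 0.03 * i, 0.7e-3)
                      for i in range(16)])
        ph = generate_dwi_phantom(16, fs, D, bval=1000, n_directions=16)
        gt = _gtab(ph)
        vol = ph.signals.reshape(4, 4, 1, -1)
        maps = map_volume(vol, gt, np.ones((4, 4, 1), bool))
        for i in range(16):
            expected = tensor_scalars(fit_bitensor(ph.signals[i], gt)).as_dict()
            for name in maps:
                assert maps[name].ravel()[i] == pytest.approx(expected[name])

    def test_grid_mismatch(self):
        ph = generate_dwi_phantom(1, 0.3, tensor_from_fa_md(0.5, 7e-4),
                                  n_directions=16)
        vol = np.tile(ph.signals[0], (2, 2, 1, 1))
        with pytest.raises(ValueError, match="grid mismatch"):
            map_volume(vol, _gtab(ph), np.ones((3, 3, 1), bool))
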