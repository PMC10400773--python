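"""Tensor fitting, derived maps and smoothing."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from dtialps.synthetic import add_rician_noise
from dtialps.tensor import (
    DiffusionTensorField,
    DWIVolume,
    GradientTable,
    GradientTableError,
    TensorMaps,
    default_gradient_table,
    derive_maps,
    design_matrix,
    fit_tensor_loglinear,
    smooth_maps,
    spread_directions,
)


def _signal_from_tensor(diag6, gtab, s0=1000.0):
    """Noise-free signal S = S0 exp(-b g^T D g) for a single tensor."""
    d = np.zeros((3, 3))
    d[0, 0], d[1, 1], d[2, 2] = diag6[:3]
    d[0, 1] = d[1, 0] = diag6[3]
    d[0, 2] = d[2, 0] = diag6[4]
    d[1, 2] = d[2, 1] = diag6[5]
    quad = np.einsum("ni,ij,nj->n", gtab.bvecs, d, gtab.bvecs)
    return s0 * np.exp(-gtab.bvals * quad)


def _single_voxel_volume(signal, voxel=2.0):
    return DWIVolume(
        data=signal.reshape(1, 1, 1, -1),
        affine=np.diag([voxel, voxel, voxel, 1.0]),
        voxel_size=np.full(3, voxel),
    )


def _fit_single(diag6, gtab):
    dwi = _single_voxel_volume(_signal_from_tensor(np.asarray(diag6), gtab))
    return fit_tensor_loglinear(dwi, gtab)


@st.composite
def spd_tensors(draw):
    """Random symmetric positive-definite tensors at diffusion scale."""
    a = np.array(draw(st.lists(st.floats(-1.0, 1.0), min_size=9, max_size=9))).reshape(3, 3)
    m = a @ a.T + 0.3 * np.eye(3)
    m *= 1e-3 / np.trace(m)  # mean diffusivity 1/3e-3
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])


class TestFit:
    def test_recovers_prolate_tensor_exactly(self, gtab):
        truth = np.array([1.7e-3, 0.3e-3, 0.3e-3, 0.0, 0.0, 0.0])
        field = _fit_single(truth, gtab)
        assert np.abs(field.coeffs[0, 0, 0] - truth).max() < 1e-9
        assert field.s0[0, 0, 0] == pytest.approx(1000.0, rel=1e-9)

    def test_isotropic_tensor_diagonal(self, gtab):
        field = _fit_single([0.8e-3] * 3 + [0.0] * 3, gtab)
        c = field.coeffs[0, 0, 0]
        assert np.allclose(c[:3], 0.8e-3, atol=1e-12)
        assert np.abs(c[3:]).max() < 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(spd_tensors())
    def test_exact_on_any_spd_tensor(self, diag6):
        gtab = default_gradient_table()
        field = _fit_single(diag6, gtab)
        assert np.abs(field.coeffs[0, 0, 0] - diag6).max() < 1e-12

    def test_insufficient_directions_rejected(self):
        dirs = np.eye(3)
        dirs = np.vstack([dirs, [np.sqrt(0.5), np.sqrt(0.5), 0.0],
                          [0.0, np.sqrt(0.5), np.sqrt(0.5)]])  # 5 distinct
        with pytest.raises(GradientTableError, match="insufficient directions"):
            GradientTable(
                bvals=np.concatenate([[0.0], np.full(5, 1000.0)]),
                bvecs=np.vstack([[0, 0, 0], dirs]),
            )

    def test_nonpositive_signal_voxel_flagged_not_fatal(self, gtab):
        sig = _signal_from_tensor(np.array([1e-3, 1e-3, 1e-3, 0, 0, 0]), gtab)
        data = np.tile(sig, (2, 1, 1, 1))
        data[1, 0, 0, 3] = 0.0  # dead voxel
        dwi = DWIVolume(data=data, affine=np.eye(4), voxel_size=np.full(3, 2.0))
        field = fit_tensor_loglinear(dwi, gtab)
        assert field.valid[0, 0, 0] and not field.valid[1, 0, 0]
        assert np.all(field.coeffs[1, 0, 0] == 0)

    def test_volume_gradient_count_mismatch(self, gtab):
        dwi = _single_voxel_volume(np.ones(gtab.n + 1))
        with pytest.raises(ValueError, match="gradient table"):
            fit_tensor_loglinear(dwi, gtab)

    def test_median_error_under_rician_noise_snr50(self, gtab):
        # 1000-voxel phantom at SNR 50: median per-element error < 5% of MD scale
        truth = np.array([1.4e-3, 0.4e-3, 0.4e-3, 0, 0, 0])
        sig = _signal_from_tensor(truth, gtab)
        data = np.tile(sig, (10, 10, 10, 1))
        noisy = add_rician_noise(data, sigma=1000.0 / 50.0, seed=7)
        dwi = DWIVolume(data=noisy, affine=np.eye(4), voxel_size=np.full(3, 2.0))
        field = fit_tensor_loglinear(dwi, gtab)
        err = np.abs(field.coeffs - truth) / truth[:3].mean()
        assert np.median(err) < 0.05


class TestDerivedMaps:
    def _field_from_coeffs(self, coeffs):
        coeffs = np.asarray(coeffs).reshape(1, 1, 1, 6)
        return DiffusionTensorField(
            coeffs=coeffs, s0=np.ones((1, 1, 1)),
            affine=np.eye(4), voxel_size=np.full(3, 2.0),
            valid=np.ones((1, 1, 1), dtype=bool),
        )

    def test_isotropic_fa_zero(self):
        maps = derive_maps(self._field_from_coeffs([1e-3] * 3 + [0.0] * 3))
        assert maps.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert maps.md[0, 0, 0] == pytest.approx(1e-3)

    def test_stick_fa_one(self):
        maps = derive_maps(self._field_from_coeffs([1e-3, 0, 0, 0, 0, 0]))
        assert maps.fa[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_tensor_fa_defined_zero(self):
        maps = derive_maps(self._field_from_coeffs([0.0] * 6))
        assert maps.fa[0, 0, 0] == 0.0
        assert np.isfinite(maps.fa).all()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(spd_tensors())
    def test_eigenvalues_match_characteristic_polynomial(self, diag6):
        maps = derive_maps(self._field_from_coeffs(diag6))
        # polynomial root-finding is ill-conditioned at (near-)repeated
        # eigenvalues; the comparison is meaningful for separated spectra
        gaps = -np.diff(maps.evals[0, 0, 0])
        assume(gaps.min() > 1e-5 * maps.evals[0, 0, 0].max())
        d = np.zeros((3, 3))
        d[0, 0], d[1, 1], d[2, 2] = diag6[:3]
        d[0, 1] = d[1, 0] = diag6[3]
        d[0, 2] = d[2, 0] = diag6[4]
        d[1, 2] = d[2, 1] = diag6[5]
        # independent oracle: roots of det(D - x I), on a unit-scale copy
        # of the tensor so the cubic is well conditioned
        ds = d * 1e3
        c2 = -np.trace(ds)
        c1 = 0.5 * (np.trace(ds) ** 2 - np.trace(ds @ ds))
        c0 = -np.linalg.det(ds)
        roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1] * 1e-3
        assert np.abs(maps.evals[0, 0, 0] - roots).max() < 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(spd_tensors(), st.integers(0, 10_000))
    def test_fa_rotation_invariant(self, diag6, rot_seed):
        rng = np.random.default_rng(rot_seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        d = np.zeros((3, 3))
        d[0, 0], d[1, 1], d[2, 2] = diag6[:3]
        d[0, 1] = d[1, 0] = diag6[3]
        d[0, 2] = d[2, 0] = diag6[4]
        d[1, 2] = d[2, 1] = diag6[5]
        dr = q @ d @ q.T
        rot6 = [dr[0, 0], dr[1, 1], dr[2, 2], dr[0, 1], dr[0, 2], dr[1, 2]]
        fa0 = derive_maps(self._field_from_coeffs(diag6)).fa[0, 0, 0]
        fa1 = derive_maps(self._field_from_coeffs(rot6)).fa[0, 0, 0]
        assert fa0 == pytest.approx(fa1, abs=1e-9)

    def test_diagonals_copied_unclamped(self):
        # a slightly indefinite (noisy) tensor keeps its raw diagonals
        coeffs = [1e-3, -1e-5, 5e-4, 0, 0, 0]
        maps = derive_maps(self._field_from_coeffs(coeffs))
        assert maps.dyy[0, 0, 0] == -1e-5
        assert (maps.evals[0, 0, 0] >= 0).all()
        assert 0 <= maps.fa[0, 0, 0] <= 1


class TestSmoothing:
    def _maps(self, arr, mask=None, voxel=2.0):
        arr = np.asarray(arr, dtype=float)
        mask = np.ones(arr.shape, dtype=bool) if mask is None else mask
        zeros = np.zeros(arr.shape)
        return TensorMaps(
            dxx=arr.copy(), dyy=zeros.copy(), dzz=zeros.copy(),
            fa=zeros.copy(), md=zeros.copy(),
            evals=np.zeros(arr.shape + (3,)),
            principal_direction=np.zeros(arr.shape + (3,)),
            affine=np.diag([voxel] * 3 + [1.0]), voxel_size=np.full(3, voxel),
            mask=mask,
        )

    def test_zero_fwhm_is_identity(self, rng):
        maps = self._maps(rng.random((8, 8, 8)))
        out = smooth_maps(maps, 0.0)
        assert np.array_equal(out.dxx, maps.dxx)

    def test_constant_preserved_inside_mask(self, rng):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        maps = self._maps(np.full((10, 10, 10), 3.14), mask=mask)
        out = smooth_maps(maps, 6.0)
        assert np.allclose(out.dxx[mask], 3.14, atol=1e-10)
        assert np.all(out.dxx[~mask] == 0)

    def test_impulse_matches_direct_gaussian(self):
        shape = (41, 41, 41)
        arr = np.zeros(shape)
        arr[20, 20, 20] = 1.0
        maps = self._maps(arr, voxel=2.0)
        fwhm = 6.0
        out = smooth_maps(maps, fwhm)
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 2.0  # voxels
        # direct evaluation: separable sampled Gaussian, normalized over the
        # same 4-sigma support the convolution uses
        radius = int(4.0 * sigma + 0.5)
        r = np.arange(-radius, radius + 1)
        k = np.zeros(41)
        k[20 - radius: 20 + radius + 1] = np.exp(-0.5 * (r / sigma) ** 2)
        k /= k.sum()
        r = np.arange(-20, 21)
        direct = k[:, None, None] * k[None, :, None] * k[None, None, :]
        center = np.array([20, 20, 20])
        offsets = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
        for off in offsets:
            i, j, l = center + np.array(off)
            assert out.dxx[i, j, l] == pytest.approx(direct[i, j, l], rel=1e-6)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_maps(self._maps(rng.random((4, 4, 4))), -1.0)


class TestGradientTable:
    def test_requires_b0(self):
        with pytest.raises(GradientTableError, match="b=0"):
            GradientTable(bvals=np.full(8, 1000.0), bvecs=spread_directions(8))

    def test_rejects_non_unit_directions(self):
        vecs = spread_directions(8) * 1.5
        with pytest.raises(GradientTableError, match="unit norm"):
            GradientTable(
                bvals=np.concatenate([[0.0], np.full(8, 1000.0)]),
                bvecs=np.vstack([[0, 0, 0], vecs]),
            )

    def test_spread_directions_well_separated(self):
        v = spread_directions(32)
        dots = np.abs(v @ v.T)
        np.fill_diagonal(dots, 0.0)
        # worst-case angular separation stays reasonable for 32 points
        assert np.degrees(np.arccos(dots.max())) > 10.0

    def test_design_matrix_full_rank(self, gtab):
        assert np.linalg.matrix_rank(design_matrix(gtab)) == 7
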