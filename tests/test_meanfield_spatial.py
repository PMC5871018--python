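"""Fourier-domain spatial solver, width calculus and feasibility."""

import numpy as np
import pytest

from imbalnet import meanfield_discrete as mfd
from imbalnet import meanfield_spatial as mfs
from imbalnet.analysis import fit_profile_width
from imbalnet.exceptions import BalanceInfeasibleError, ParameterError
from imbalnet.model_parameters import MV_MS_TO_MV_S


@pytest.fixture(scope="module")
def kernels():
    return mfs.default_spatial_kernels()


class TestKernelFourier:
    def test_zero_mode_equals_total_weight(self, kernels):
        Wt, WtX = mfs.kernel_fourier(kernels, (8, 8, 4))
        np.testing.assert_allclose(Wt[:, :, 0, 0, 0], kernels.W0)
        np.testing.assert_allclose(WtX[:, 0, 0, 0], kernels.W0_X)

    def test_first_spatial_mode_attenuation(self, kernels):
        # exp(-2 pi^2 * 0.15^2) for the excitatory column at n = (1, 0)
        Wt, _ = mfs.kernel_fourier(kernels, (8, 8, 4))
        ratio = Wt[0, 0, 1, 0, 0] / kernels.wbar[("E", "E")]
        assert ratio == pytest.approx(np.exp(-2 * np.pi**2 * 0.0225), rel=1e-12)
        assert ratio == pytest.approx(0.6414, abs=5e-4)

    def test_strictly_decreasing_in_frequency(self, kernels):
        Wt, _ = mfs.kernel_fourier(kernels, (16, 16, 8))
        along_n = Wt[0, 0, :8, 0, 0]
        along_k = Wt[0, 0, 0, 0, :4]
        assert np.all(np.diff(along_n) < 0)
        assert np.all(np.diff(along_k) < 0)


class TestStimulus:
    def test_unit_floors_give_uniform_field(self):
        spec = mfs.StimulusSpec(c=1.0, c_theta=1.0, rbar_X=7.0, calibrate=False)
        f = mfs.build_stimulus(spec, (8, 8, 4))
        np.testing.assert_allclose(f, 7.0)

    def test_calibrated_spatial_factor_hits_bounds(self):
        for sx in (0.2, 0.06):
            F = mfs._spatial_factor(mfs.StimulusSpec(sigma_X=sx), (64, 64, 8))
            assert F.min() == pytest.approx(10.0)
            assert F.max() == pytest.approx(20.0)

    def test_disc_center_and_far_field(self):
        spec = mfs.StimulusSpec(
            variant="disc", sigma_X=0.2, edge_blur=0.0, calibrate=True,
            r_min=10.0, r_max=20.0,
        )
        f = mfs.build_stimulus(spec, (64, 64, 1))
        assert f[32, 32, 0] == pytest.approx(20.0)
        assert f[0, 0, 0] == pytest.approx(10.0)

    def test_negative_contrast_rejected(self):
        cmap = -np.ones((8, 8))
        spec = mfs.StimulusSpec(variant="contrast_map", contrast_map=cmap)
        with pytest.raises(ParameterError):
            mfs.build_stimulus(spec, (8, 8, 1))


class TestGaussianWidths:
    def test_no_divergence_collapses_widths(self):
        wm = mfs.gaussian_widths(0.1, 0.0, 0.0, 0.0)
        assert wm.beta_X == pytest.approx(0.1)
        assert wm.sigma_E == pytest.approx(0.1)
        assert wm.sigma_I == pytest.approx(0.1)

    def test_reference_visual_cortex_values(self):
        wm = mfs.gaussian_widths(0.2, 0.04, 0.15, 0.04)
        assert wm.feasible
        assert wm.beta_X == pytest.approx(0.2040, abs=5e-5)
        assert wm.sigma_E == pytest.approx(0.1382, abs=5e-5)
        assert wm.sigma_I == pytest.approx(0.2000, abs=5e-5)

    def test_narrow_stimulus_is_infeasible(self):
        wm = mfs.gaussian_widths(0.06, 0.04, 0.15, 0.04)
        assert not wm.feasible
        assert wm.beta_X == pytest.approx(0.0721, abs=5e-5)
        assert wm.sigma_E is None


class TestCorrectedSolver:
    def test_uniform_stimulus_reduces_to_discrete(self, kernels):
        rX = np.full((16, 16, 4), 5.0)
        r = mfs.spatial_corrected_rates(kernels, rX, epsilon=1e-3, g=10.0)
        rd = mfd.corrected_rates(kernels.W0, kernels.W0_X * 5.0, 1e-3, 10.0).r
        np.testing.assert_allclose(r[0], rd[0], rtol=1e-12)
        np.testing.assert_allclose(r[1], rd[1], rtol=1e-12)

    def test_matches_dense_real_space_oracle(self, kernels):
        # explicit circular-convolution matrices on a coarse grid
        shape = (16, 16, 8)
        M = int(np.prod(shape))
        eps, g = 1e-3, 10.0
        rng = np.random.default_rng(3)
        modes = np.zeros(shape, complex)
        n1, n2, k = mfs._mode_numbers(shape)
        sel = (np.abs(n1) <= 3) & (np.abs(n2) <= 3) & (np.abs(k) <= 2)
        modes[sel] = (rng.normal(size=shape) + 1j * rng.normal(size=shape))[sel]
        f = np.fft.ifftn(modes).real
        rX = 10 + 5 * (f - f.min()) / (f.max() - f.min())

        r_fft = mfs.spatial_corrected_rates(kernels, rX, epsilon=eps, g=g)

        Wt, WtX = mfs.kernel_fourier(kernels, shape)
        gx, gy, gt = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        coords = np.stack([gx.ravel(), gy.ravel(), gt.ravel()])
        di = (coords[:, :, None] - coords[:, None, :]) % np.array(shape)[:, None, None]

        def circulant(block_modes):
            wreal = np.fft.ifftn(block_modes * M).real
            return wreal[di[0], di[1], di[2]] / M

        A = np.zeros((2 * M, 2 * M))
        for i in range(2):
            for j in range(2):
                A[i * M:(i + 1) * M, j * M:(j + 1) * M] = -circulant(Wt[i, j])
        A += eps * MV_MS_TO_MV_S / g * np.eye(2 * M)
        X = np.concatenate(
            [circulant(WtX[0]) @ rX.ravel(), circulant(WtX[1]) @ rX.ravel()]
        )
        r_dense = np.linalg.solve(A, X)
        got = np.concatenate([r_fft[0].ravel(), r_fft[1].ravel()])
        assert np.linalg.norm(got - r_dense) <= 1e-8 * np.linalg.norm(r_dense)

    def test_mode_zero_identity(self, kernels):
        rX = mfs.build_stimulus(mfs.StimulusSpec(sigma_X=0.1), (32, 32, 8))
        eps, g = 1e-4, 12.0
        r = mfs.spatial_corrected_rates(kernels, rX, epsilon=eps, g=g)
        rd = mfd.corrected_rates(kernels.W0, kernels.W0_X * rX.mean(), eps, g).r
        assert r[0].mean() == pytest.approx(rd[0], rel=1e-10)
        assert r[1].mean() == pytest.approx(rd[1], rel=1e-10)

    def test_narrow_stimulus_surround_suppression(self, kernels):
        shape = (48, 48, 8)
        broad = mfs.spatial_corrected_rates(
            kernels, mfs.build_stimulus(mfs.StimulusSpec(sigma_X=0.2), shape), g=12.0
        )
        narrow = mfs.spatial_corrected_rates(
            kernels, mfs.build_stimulus(mfs.StimulusSpec(sigma_X=0.06), shape), g=12.0
        )
        line_b = broad[0][:, 24, :].mean(-1)
        line_n = narrow[0][:, 24, :].mean(-1)
        assert line_n.max() > line_b.max()  # amplified center peak
        flank = 24 + 6
        assert line_n[flank] < line_b[flank]  # suppressed flanks

    def test_local_imbalance_with_global_balance(self, kernels):
        # center-peak deviation grows like 1/eps while the domain average
        # stays pinned near the uniform balanced value
        shape = (48, 48, 1)
        rX = mfs.build_stimulus(mfs.StimulusSpec(sigma_X=0.06), shape)
        bal0 = mfd.balanced_rates(kernels.W0, kernels.W0_X * rX.mean()).r[0]
        ratios = []
        for eps in (1e-3, 1e-4, 1e-5):
            r = mfs.spatial_corrected_rates(kernels, rX, epsilon=eps, g=12.0)
            avg = r[0].mean()
            ratios.append(abs(r[0][24, 24, 0] - avg) / abs(avg - bal0))
        assert ratios[0] < ratios[1] < ratios[2]


class TestBalancedSolver:
    def test_uniform_stimulus_reduces_to_discrete(self, kernels):
        rX = np.full((16, 16, 4), 5.0)
        r = mfs.spatial_balanced_rates(kernels, rX)
        rd = mfd.balanced_rates(kernels.W0, kernels.W0_X * 5.0).r
        np.testing.assert_allclose(r[0], rd[0], rtol=1e-10)
        np.testing.assert_allclose(r[1], rd[1], rtol=1e-10)

    @pytest.mark.parametrize("sigma_X,shape", [(0.2, (64, 64, 8)), (0.25, (48, 48, 4))])
    def test_width_recovery_matches_calculus(self, kernels, sigma_X, shape):
        rX = mfs.build_stimulus(mfs.StimulusSpec(sigma_X=sigma_X), shape)
        r = mfs.spatial_balanced_rates(kernels, rX)
        wm = mfs.gaussian_widths(
            sigma_X, kernels.alpha["X"], kernels.alpha["E"], kernels.alpha["I"]
        )
        grid_h = 1.0 / shape[0]
        assert fit_profile_width(r[0], axis=0)["sigma"] == pytest.approx(
            wm.sigma_E, abs=grid_h
        )
        assert fit_profile_width(r[1], axis=0)["sigma"] == pytest.approx(
            wm.sigma_I, abs=grid_h
        )

    def test_sharp_input_refused(self, kernels):
        rX = mfs.build_stimulus(mfs.StimulusSpec(sigma_X=0.06), (64, 64, 8))
        with pytest.raises(BalanceInfeasibleError, match="cannot be realized"):
            mfs.spatial_balanced_rates(kernels, rX)

    def test_corrected_converges_to_balanced_for_feasible_input(self, kernels):
        shape = (32, 32, 4)
        rX = mfs.build_stimulus(mfs.StimulusSpec(sigma_X=0.2), shape)
        target = mfs.spatial_balanced_rates(kernels, rX)
        errs = []
        for eps in (1e-4, 1e-5, 1e-6):
            r = mfs.spatial_corrected_rates(kernels, rX, epsilon=eps, g=12.0)
            errs.append(np.max(np.abs(r - target)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[-1] < 1e-2 * np.max(np.abs(target))


class TestSizeTuningAndSharpness:
    def test_constant_field_has_zero_sharpness(self):
        assert mfs.sharpness_index(np.full((16, 16), 3.0)) == 0.0

    def test_step_field_sharpness_is_height_times_n(self):
        f = np.zeros((20, 20))
        f[:10, :] = 2.0
        assert mfs.sharpness_index(f, axis=0) == pytest.approx(2.0 * 20)

    def test_broad_excitation_gives_single_interior_maximum(self, kernels):
        scan = mfs.size_tuning_scan(
            kernels, np.linspace(0.02, 0.3, 15), g=12.0, shape=(48, 48, 1)
        )
        assert scan["n_maxima_E"] == 1
        assert scan["monotone_I"]

    def test_field_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        f = rng.random((6, 5, 3))
        path = str(tmp_path / "field.csv")
        mfs.field_to_csv(f, path)
        np.testing.assert_allclose(mfs.field_from_csv(path), f)
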