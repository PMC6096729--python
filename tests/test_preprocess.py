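import numpy as np
import pytest
from scipy import ndimage

import nucshuttle as ns
from nucshuttle import preprocess


def make_stack(data, voxel=(0.5, 0.2, 0.2), names=None):
    data = np.asarray(data, dtype=float)
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    return ns.VolumeStack(data, voxel, names)


class TestBackgroundLines:
    def test_constant_field_recovered_exactly(self):
        st = make_stack(np.full((1, 6, 40, 60), 100.0))
        lines = [
            np.array([[1.0, 2.0, 1.0], [1.0, 2.0, 9.0]]),
            np.array([[2.0, 4.0, 2.0], [2.0, 4.0, 10.0]]),
        ]
        est = preprocess.estimate_background_lines(st, "ch0", lines=lines)
        assert est.mean["ch0"] == pytest.approx(100.0)
        assert est.sd["ch0"] == 0.0

    def test_estimate_is_mean_of_per_line_means(self):
        data = np.zeros((1, 4, 20, 60))
        data[0, 1] = 10.0  # line 1 plane
        data[0, 2] = 30.0  # line 2 plane
        st = make_stack(data)
        lines = [
            np.array([[0.5, 1.0, 1.0], [0.5, 1.0, 9.0]]),
            np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 9.0]]),
        ]
        est = preprocess.estimate_background_lines(st, "ch0", lines=lines)
        assert est.line_means["ch0"] == [pytest.approx(10.0), pytest.approx(30.0)]
        assert est.mean["ch0"] == pytest.approx(20.0)

    def test_line_outside_volume_rejected(self):
        st = make_stack(np.zeros((1, 4, 10, 10)))
        line = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]])
        with pytest.raises(ValueError, match="leaves the stack"):
            preprocess.estimate_background_lines(st, "ch0", lines=[line])

    def test_phantom_background_recovered_within_noise(self, rendered_stack):
        """Auto-placed off-cell lines recover the configured background level."""
        optics = ns.OpticsParams()
        est = preprocess.estimate_background_lines(rendered_stack, seed=3)
        # Poisson + read noise SD per voxel at the background level
        sd = np.sqrt(
            optics.background_level / optics.photon_scale + optics.read_noise_sd**2
        )
        for ch in rendered_stack.channel_names:
            assert abs(est.mean[ch] - optics.background_level) < 3 * sd


class TestMeanFilter:
    def test_radius_zero_is_identity(self, tiny_stack):
        out = preprocess.mean_filter(tiny_stack, 0)
        assert np.array_equal(out.data, tiny_stack.data)

    def test_constant_stack_unchanged(self):
        st = make_stack(np.full((1, 3, 10, 10), 42.0))
        out = preprocess.mean_filter(st, 2)
        np.testing.assert_allclose(out.data, 42.0)

    def test_single_voxel_spreads_in_plane_only(self):
        data = np.zeros((1, 3, 11, 11))
        data[0, 1, 5, 5] = 900.0
        st = make_stack(data)
        out = preprocess.mean_filter(st, 1).data[0]
        # direct convolution oracle: 3x3 in-plane box
        expected = ndimage.convolve(
            data[0], np.full((1, 3, 3), 1 / 9.0), mode="reflect"
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[0].sum() == 0 and out[2].sum() == 0  # no z leakage
        assert out[1].sum() == pytest.approx(900.0)

    def test_3d_mode_spreads_across_planes(self):
        data = np.zeros((1, 5, 5, 5))
        data[0, 2, 2, 2] = 27.0
        out = preprocess.mean_filter(make_stack(data), 1, mode="3d").data[0]
        assert out[1, 2, 2] == pytest.approx(1.0)


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, tiny_stack):
        psf = np.zeros((3, 3, 3))
        psf[1, 1, 1] = 1.0
        out = preprocess.richardson_lucy(tiny_stack.astype_float(), psf, 10)
        np.testing.assert_allclose(out.data, tiny_stack.data, rtol=1e-12)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(0)
        st = make_stack(rng.uniform(0, 50, (1, 10, 12, 12)))
        psf = preprocess.gaussian_psf((0.5, 0.3, 0.3), st.voxel_size)
        out = preprocess.richardson_lucy(st, psf, 15)
        assert out.data.min() >= 0

    def test_deblurs_point_source_and_conserves_mass(self):
        """Forward-blur oracle: RL sharpens the peak and keeps total grey."""
        obj = np.zeros((21, 21, 21))
        obj[10, 10, 10] = 1000.0
        psf = preprocess.gaussian_psf((0.4, 0.4, 0.4), (0.2, 0.2, 0.2))
        blurred = ndimage.convolve(obj, psf, mode="mirror")
        st = make_stack(blurred[None], voxel=(0.2, 0.2, 0.2))
        dec = preprocess.richardson_lucy(st, psf, 50).data[0]
        width = lambda x: (x > x.max() / 2).sum()
        assert width(dec) < width(blurred)
        assert dec.sum() == pytest.approx(blurred.sum(), rel=0.01)

    def test_poisson_deviance_monotone(self):
        """RL non-increases the Poisson deviance on a noiseless problem."""
        obj = np.zeros((15, 15, 15))
        obj[7, 7, 7] = 500.0
        obj[4, 9, 6] = 300.0
        psf = preprocess.gaussian_psf((0.3, 0.3, 0.3), (0.2, 0.2, 0.2))
        data = ndimage.convolve(obj, psf, mode="mirror")
        st = make_stack(data[None], voxel=(0.2, 0.2, 0.2))

        def deviance(est):
            fwd = ndimage.convolve(est, psf, mode="mirror")
            eps = 1e-12
            return float(np.sum(fwd - data + data * np.log((data + eps) / (fwd + eps))))

        devs = [
            deviance(preprocess.richardson_lucy(st, psf, i).data[0])
            for i in range(1, 21)
        ]
        assert np.all(np.diff(devs) <= 1e-9)

    def test_agrees_with_reference_implementation(self):
        """Interior voxels match skimage's RL (independent implementation)."""
        from skimage.restoration import richardson_lucy as sk_rl

        obj = np.zeros((21, 21, 21))
        obj[10, 10, 10] = 1000.0
        psf = preprocess.gaussian_psf((0.4, 0.4, 0.4), (0.2, 0.2, 0.2))
        blurred = ndimage.convolve(obj, psf, mode="mirror")
        ours = preprocess.richardson_lucy(
            make_stack(blurred[None], voxel=(0.2, 0.2, 0.2)), psf, 20
        ).data[0]
        ref = sk_rl(blurred / blurred.max(), psf, num_iter=20, clip=False)
        ref *= blurred.max()
        inner = (slice(6, 15),) * 3
        np.testing.assert_allclose(ours[inner], ref[inner], atol=1e-4 * ref.max())

    def test_invalid_psf_rejected(self, tiny_stack):
        with pytest.raises(ValueError, match="positive total"):
            preprocess.richardson_lucy(tiny_stack, np.zeros((3, 3, 3)), 5)
        with pytest.raises(ValueError, match="non-negative"):
            preprocess.richardson_lucy(tiny_stack, -np.ones((3, 3, 3)), 5)
        with pytest.raises(ValueError, match="larger than the stack"):
            preprocess.richardson_lucy(tiny_stack, np.ones((30, 30, 30)) / 27e3, 5)
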