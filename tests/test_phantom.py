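import math

import numpy as np
import pytest

import nucshuttle as ns
from nucshuttle import phantom


class TestBuildScene:
    def test_half_volume_nucleus_gives_equal_densities(self):
        """Target 0.5 with a nucleus of half the soma volume implies symmetry."""
        soma = (4.0, 4.5, 4.5)
        nucleus = tuple(a * 0.5 ** (1 / 3) for a in soma)
        scene = ns.build_scene(
            target_nuclear_fraction=0.5,
            soma_semiaxes=soma,
            nucleus_semiaxes=nucleus,
        )
        conc = scene.concentrations["reporter"]
        assert conc["nucleus"] == pytest.approx(conc["cytoplasm"], rel=1e-9)

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.782, 0.95])
    def test_truth_fraction_solved_exactly(self, target):
        scene = ns.build_scene(target_nuclear_fraction=target, seed=0)
        assert scene.nuclear_fraction() == pytest.approx(target, abs=1e-6)

    def test_truth_agrees_with_brute_force_integration(self):
        """Stored truth matches supersampled grid integration within 1e-3."""
        scene = ns.build_scene(
            target_nuclear_fraction=0.782,
            granule_radii=(0.4, 0.3, 0.25),
            seed=3,
        )
        numeric = scene.nuclear_fraction_numeric(supersample=4)
        assert numeric == pytest.approx(scene.nuclear_fraction_truth, abs=1e-3)

    def test_seed_determinism_of_granule_placement(self):
        radii = (0.3, 0.25, 0.2, 0.2)
        a = ns.build_scene(target_nuclear_fraction=0.5, granule_radii=radii, seed=9)
        b = ns.build_scene(target_nuclear_fraction=0.5, granule_radii=radii, seed=9)
        c = ns.build_scene(target_nuclear_fraction=0.5, granule_radii=radii, seed=10)
        assert all(
            ga.center == gb.center for ga, gb in zip(a.granules, b.granules)
        )
        assert any(
            ga.center != gc.center for ga, gc in zip(a.granules, c.granules)
        )

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="not inside soma"):
            ns.build_scene(
                target_nuclear_fraction=0.5,
                soma_semiaxes=(3.0, 3.0, 3.0),
                nucleus_semiaxes=(4.0, 4.0, 4.0),
            )
        with pytest.raises(ValueError, match="target_nuclear_fraction"):
            ns.build_scene(target_nuclear_fraction=1.0)

    def test_granules_must_fit_nucleus(self):
        with pytest.raises(ValueError, match="does not fit"):
            ns.build_scene(target_nuclear_fraction=0.5, granule_radii=(5.0,))


class TestRender:
    def test_uniform_soma_total_matches_analytic_volume(self):
        """Summed grey of a uniform compartment tracks the ellipsoid volume."""
        scene = ns.build_scene(target_nuclear_fraction=0.5, seed=0)
        voxel = (0.2, 0.2, 0.2)
        shape = ns.grid_for_scene(scene, voxel)
        optics = ns.OpticsParams(
            psf_sigma=(0.02, 0.02, 0.02),
            photon_scale=None, read_noise_sd=0.0, background_level=0.0,
        )
        stack = ns.render(scene, optics, shape, voxel, seed=None)
        density = scene.concentrations["cytoplasm"]["cytoplasm"]
        expected = density * scene.soma.volume / np.prod(voxel)
        assert stack.channel("cytoplasm").sum() == pytest.approx(expected, rel=0.01)

    def test_psf_blur_conserves_mass_away_from_boundaries(self, noiseless_stack,
                                                          default_scene):
        voxel = (0.4, 0.2, 0.2)
        shape = ns.grid_for_scene(default_scene, voxel)
        sharp = ns.render(
            default_scene,
            ns.OpticsParams(psf_sigma=(0.02, 0.02, 0.02), photon_scale=None,
                            read_noise_sd=0.0, background_level=0.0),
            shape, voxel, seed=None,
        )
        blurred = noiseless_stack
        for ch in ("reporter", "nuclear"):
            a, b = sharp.channel(ch).sum(), blurred.channel(ch).sum()
            assert b == pytest.approx(a, rel=0.005)

    def test_seeded_render_deterministic(self, default_scene):
        voxel = (0.4, 0.2, 0.2)
        shape = ns.grid_for_scene(default_scene, voxel)
        a = ns.render(default_scene, ns.OpticsParams(), shape, voxel, seed=5)
        b = ns.render(default_scene, ns.OpticsParams(), shape, voxel, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_scene_beyond_grid_flagged(self, default_scene):
        with pytest.raises(ValueError, match="beyond grid"):
            ns.render(
                default_scene, ns.OpticsParams(), (4, 8, 8), (0.4, 0.2, 0.2),
                out_of_grid="error",
            )


class TestUVBleach:
    def _uniform(self):
        return ns.VolumeStack(
            np.full((1, 4, 160, 160), 500.0), (1.0, 0.25, 0.25), ("ch",)
        )

    def test_half_attenuation_at_nominal_radius(self):
        st = self._uniform()
        post = ns.apply_uv_bleach(st, (20.0, 20.0), 10.0)
        # sample attenuation on a ring of radius 10 µm
        dy, dx = 0.25, 0.25
        yy = np.arange(160) * dy - 20.0
        xx = np.arange(160) * dx - 20.0
        r = np.sqrt(yy[:, None] ** 2 + xx[None, :] ** 2)
        ring = np.abs(r - 10.0) < 0.1
        att = 1 - post.channel("ch")[0][ring] / 500.0
        assert att.mean() == pytest.approx(0.5, abs=0.02)

    def test_far_field_attenuation_vanishes(self):
        surv = phantom.bleach_survival(np.array([1e3]), 10.0)
        assert 1 - surv[0] == pytest.approx(0.0, abs=1e-12)

    def test_axial_symmetry(self):
        st = self._uniform()
        post = ns.apply_uv_bleach(st, (20.0, 20.0), 10.0).channel("ch")[0]
        c = 80  # voxel index of the centre
        off = 20
        four = [post[c - off, c], post[c + off, c], post[c, c - off], post[c, c + off]]
        assert np.ptp(four) < 1e-9

    def test_column_outside_fov_rejected(self):
        with pytest.raises(ValueError, match="outside the field of view"):
            ns.apply_uv_bleach(self._uniform(), (500.0, 20.0), 10.0)

    def test_floor_above_half_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            phantom.bleach_survival(5.0, 10.0, floor=0.6)


class TestDegeneration:
    VOXEL = (0.4, 0.2, 0.2)

    def test_zero_redistribution_keeps_fraction_constant(self):
        scene = ns.build_scene(target_nuclear_fraction=0.782, seed=2)
        deg = ns.DegenerationParams(
            t_expand_end=1800.0, dissolution_time=7200.0,
            redistribution_curve=lambda t: 0.0,
        )
        _, truth = ns.simulate_degeneration(
            scene, deg, ns.OpticsParams(), [0.0, 600.0, 1500.0], seed=0,
            voxel_size=self.VOXEL, noise=False,
        )
        assert np.allclose(truth.nuclear_fraction, 0.782, atol=1e-9)

    def test_pyknosis_conserves_rendered_reporter_mass(self):
        """Total rendered reporter stays within 1% frame to frame pre-dissolution."""
        scene = ns.build_scene(target_nuclear_fraction=0.782, seed=7)
        deg = ns.DegenerationParams(t_expand_end=1800.0, dissolution_time=7200.0)
        optics = ns.OpticsParams(
            background_level=0.0, read_noise_sd=0.0, photon_scale=None
        )
        shape = tuple(
            int(s * 1.6) for s in ns.grid_for_scene(scene, self.VOXEL)
        )
        tl, truth = ns.simulate_degeneration(
            scene, deg, optics, [0.0, 3000.0, 6000.0], seed=1,
            shape=shape, voxel_size=self.VOXEL, noise=False,
        )
        sums = [f.channel("reporter").sum() for f in tl.frames]
        assert np.ptp(sums) / max(sums) < 0.01
        assert np.ptp(truth.reporter_total_mass) < 1e-6 * truth.reporter_total_mass[0]

    def test_dissolution_removes_cytoplasmic_signal(self):
        scene = ns.build_scene(target_nuclear_fraction=0.782, seed=2)
        deg = ns.DegenerationParams(t_expand_end=1800.0, dissolution_time=3600.0)
        optics = ns.OpticsParams(
            background_level=0.0, read_noise_sd=0.0, photon_scale=None
        )
        shape = tuple(int(s * 1.6) for s in ns.grid_for_scene(scene, self.VOXEL))
        tl, _ = ns.simulate_degeneration(
            scene, deg, optics, [0.0, 4000.0], seed=1,
            shape=shape, voxel_size=self.VOXEL, noise=False,
        )
        assert tl.frames[1].channel("cytoplasm").sum() < 1e-6

    def test_axonal_truth_peaks_at_spike_time(self):
        scene = ns.build_scene(target_nuclear_fraction=0.782, seed=2)
        scene.axon = ns.default_axon(scene.soma)
        spike = 5 * 3600.0
        deg = ns.DegenerationParams(
            t_expand_end=3600.0, dissolution_time=spike + 3600.0,
            axonal_influx=ns.AxonalInflux(onset_s=7200.0, spike_s=spike),
        )
        ts = np.arange(0.0, spike + 1800.0, 900.0)
        _, truth = ns.simulate_degeneration(
            scene, deg, ns.OpticsParams(), ts, seed=0,
            shape=(8, 16, 16), voxel_size=(2.0, 4.0, 8.0), noise=False,
        )
        peak_t = truth.time_s[truth.axon_mean_density.idxmax()]
        assert abs(peak_t - spike) <= 900.0 / 2

    def test_bad_timestamps_rejected(self):
        scene = ns.build_scene(target_nuclear_fraction=0.5, seed=0)
        deg = ns.DegenerationParams()
        with pytest.raises(ValueError, match="strictly increasing"):
            ns.simulate_degeneration(
                scene, deg, ns.OpticsParams(), [0.0, 0.0], seed=0
            )
        with pytest.raises(ValueError, match="horizon"):
            ns.simulate_degeneration(
                scene, deg, ns.OpticsParams(), [0.0, 1e9], seed=0
            )

    def test_dissolution_must_follow_expansion(self):
        with pytest.raises(ValueError, match="dissolution_time"):
            ns.DegenerationParams(t_expand_end=3600.0, dissolution_time=1800.0)
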