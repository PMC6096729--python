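import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import kendalltau

import nucshuttle as ns
from nucshuttle import compartment, preprocess
from nucshuttle.phantom import _ellipsoid_occupancy


def two_level_stack(low=0, high=1000):
    data = np.full((1, 6, 10, 10), low, dtype=np.uint16)
    data[0, 2:4, 3:7, 3:7] = high
    return ns.VolumeStack(data, (0.5, 0.2, 0.2), ("ch",))


class TestSegmentChannel:
    def test_otsu_separates_bimodal(self):
        st = two_level_stack()
        mask = compartment.segment_channel(st, "ch", "otsu")
        assert np.array_equal(mask, st.channel("ch") == 1000)

    def test_fixed_threshold_matches(self):
        st = two_level_stack()
        a = compartment.segment_channel(st, "ch", "otsu")
        b = compartment.segment_channel(st, "ch", "fixed:500")
        c = compartment.segment_channel(st, "ch", 500)
        assert np.array_equal(a, b) and np.array_equal(b, c)

    def test_small_objects_removed(self):
        data = np.zeros((1, 6, 10, 10), dtype=np.uint16)
        data[0, 2:4, 3:7, 3:7] = 1000  # 32 voxels
        data[0, 0, 0, 0] = 1000  # lone voxel
        st = ns.VolumeStack(data, (0.5, 0.2, 0.2), ("ch",))
        mask = compartment.segment_channel(st, "ch", 500, min_object_voxels=4)
        assert mask.sum() == 32

    def test_phantom_nucleus_volume_within_10pct(self, rendered_stack,
                                                 default_scene):
        mask = compartment.segment_channel(rendered_stack, "nuclear")
        vol = mask.sum() * rendered_stack.voxel_volume_um3
        assert vol == pytest.approx(default_scene.nucleus.volume, rel=0.10)


class TestMasksInvariants:
    def test_nuclear_subset_enforced(self):
        soma = np.zeros((2, 4, 4), bool)
        soma[0] = True
        nuc = np.ones((2, 4, 4), bool)
        with pytest.raises(ValueError, match="subset"):
            compartment.CompartmentMasks(soma, nuc, soma & ~nuc)

    def test_cytoplasm_is_complement(self):
        soma = np.ones((2, 4, 4), bool)
        nuc = np.zeros((2, 4, 4), bool)
        nuc[0, 0, 0] = True
        with pytest.raises(ValueError, match="soma minus nucleus"):
            compartment.CompartmentMasks(soma, nuc, soma)


def manual_masks(shape, nuc_slice):
    soma = np.ones(shape, bool)
    nuc = np.zeros(shape, bool)
    nuc[nuc_slice] = True
    return compartment.CompartmentMasks(soma, nuc, soma & ~nuc)


class TestPartition:
    def test_uniform_reporter_half_volume_nucleus(self):
        data = np.full((1, 4, 4, 4), 7.0)
        st = ns.VolumeStack(data, (1, 1, 1), ("rep",))
        masks = manual_masks((4, 4, 4), (slice(0, 2), slice(None), slice(None)))
        res = compartment.partition(st, "rep", masks)
        assert res.nuclear_fraction == pytest.approx(0.5)

    def test_all_reporter_in_nucleus(self):
        data = np.zeros((1, 4, 4, 4))
        data[0, 0] = 100.0
        st = ns.VolumeStack(data, (1, 1, 1), ("rep",))
        masks = manual_masks((4, 4, 4), (slice(0, 1), slice(None), slice(None)))
        res = compartment.partition(st, "rep", masks)
        assert res.nuclear_fraction == 1.0

    def test_integer_additivity_bit_exact(self, tiny_stack):
        masks = manual_masks(
            tiny_stack.shape_zyx, (slice(0, 3), slice(None), slice(None))
        )
        res = compartment.partition(tiny_stack, "reporter", masks)
        soma_sum = int(
            tiny_stack.channel("reporter")[masks.soma_mask].sum(dtype=np.int64)
        )
        assert res.nuclear_sum + res.cytoplasmic_sum == soma_sum
        assert isinstance(res.nuclear_sum, int)

    def test_fraction_invariant_under_rescaling(self, tiny_stack):
        masks = manual_masks(
            tiny_stack.shape_zyx, (slice(0, 3), slice(None), slice(None))
        )
        r1 = compartment.partition(tiny_stack, "reporter", masks)
        scaled = tiny_stack.with_data(tiny_stack.data.astype(float) * 37.5)
        r2 = compartment.partition(scaled, "reporter", masks)
        assert r1.nuclear_fraction == pytest.approx(r2.nuclear_fraction, abs=1e-12)

    def test_zero_total_is_explicit_error(self):
        st = ns.VolumeStack(np.zeros((1, 4, 4, 4)), (1, 1, 1), ("rep",))
        masks = manual_masks((4, 4, 4), (slice(0, 2), slice(None), slice(None)))
        with pytest.raises(ValueError, match="fraction undefined"):
            compartment.partition(st, "rep", masks)

    def test_empty_soma_is_error(self):
        st = ns.VolumeStack(np.ones((1, 4, 4, 4)), (1, 1, 1), ("rep",))
        empty = np.zeros((4, 4, 4), bool)
        masks = compartment.CompartmentMasks(empty, empty.copy(), empty.copy())
        with pytest.raises(ValueError, match="empty"):
            compartment.partition(st, "rep", masks)

    def test_phantom_recovery_at_published_fraction(self, rendered_stack):
        """Target 78.2% nuclear localisation recovered within ±0.05."""
        masks = compartment.compute_masks(rendered_stack)
        bg = preprocess.estimate_background_lines(rendered_stack, seed=0)
        res = compartment.partition(rendered_stack, "reporter", masks, background=bg)
        assert res.nuclear_fraction == pytest.approx(0.782, abs=0.05)


class TestTimecourse:
    VOXEL = (0.4, 0.2, 0.2)

    def test_monotone_redistribution_measured_decreasing(self):
        scene = ns.build_scene(target_nuclear_fraction=0.782, seed=5)
        deg = ns.DegenerationParams(t_expand_end=3600.0, dissolution_time=7200.0)
        ts = np.arange(0, 3700, 360.0)  # 11 frames
        tl, _ = ns.simulate_degeneration(
            scene, deg, ns.OpticsParams(), ts, seed=21, voxel_size=self.VOXEL
        )
        res = compartment.partition_timecourse(tl)
        fr = [r.nuclear_fraction for r in res]
        tau, p = kendalltau(ts, fr)
        assert tau < 0 and p < 0.01

    def test_static_phantom_constant_within_003(self, default_scene):
        shape = ns.grid_for_scene(default_scene, self.VOXEL)
        frames = [
            ns.render(default_scene, ns.OpticsParams(), shape, self.VOXEL, seed=s)
            for s in range(6)
        ]
        tl = ns.TimeLapse(frames, np.arange(6.0) * 50.0)
        res = compartment.partition_timecourse(tl)
        fr = np.array([r.nuclear_fraction for r in res])
        assert np.ptp(fr) < 0.03

    def test_karyorrhexis_splits_nuclear_mask(self):
        scene = ns.build_scene(target_nuclear_fraction=0.782, seed=6)
        deg = ns.DegenerationParams(
            nuclear_fate="karyorrhexis", t_expand_end=1800.0,
            fate_onset=1800.0, dissolution_time=7200.0,
        )
        tl, truth = ns.simulate_degeneration(
            scene, deg, ns.OpticsParams(), [0.0, 5400.0, 6900.0], seed=31,
            voxel_size=self.VOXEL,
        )
        late = tl.frames[-1]
        masks = compartment.compute_masks(late)
        _, n = ndimage.label(masks.nuclear_mask, structure=np.ones((3, 3, 3), bool))
        assert truth.nuclear_bodies.iloc[-1] >= 2
        assert n >= 2

    def test_per_frame_errors_carry_frame_index(self, tiny_stack):
        dark = tiny_stack.with_data(np.zeros_like(tiny_stack.data))
        tl = ns.TimeLapse([dark, dark], [0.0, 50.0])
        with pytest.raises(ValueError, match="frame 0"):
            compartment.partition_timecourse(
                tl, reporter="reporter", nuclear_channel="nuclear",
                soma_channel="reporter",
            )
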