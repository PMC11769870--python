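"""T2 fitting, depth computation, laminar partition and aggregation."""

import numpy as np
import pytest

from lamt2 import t2map
from lamt2.io import LabelMask, MESEVolume
from lamt2.phantom import simulate_signal
from lamt2.t2map import (
    LAYER_DEEP,
    LAYER_SUPERFICIAL,
    LayerPartition,
    RegionalT2,
    T2Map,
    aggregate,
    compute_depth,
    fit_t2,
    fit_t2_signals,
    partition_layers,
)

TE = (10, 20, 30, 40, 50, 60, 70)
SPACING = (3.5, 1.0, 1.0)


class TestFit:
    def test_noiseless_roundtrip(self):
        sig = simulate_signal(40.0, 100.0, TE)
        t2, s0, valid = fit_t2_signals(sig, TE)
        assert valid[0]
        assert t2[0] == pytest.approx(40.0, rel=1e-6)
        assert s0[0] == pytest.approx(100.0, rel=1e-6)

    def test_constant_signal_invalid(self):
        t2, _, valid = fit_t2_signals(np.full(7, 80.0), TE)
        assert not valid[0]

    def test_above_cap_invalid(self):
        sig = simulate_signal(250.0, 100.0, TE)
        _, _, valid = fit_t2_signals(sig, TE, t2_cap=100.0)
        assert not valid[0]

    def test_too_few_echoes(self):
        with pytest.raises(ValueError):
            fit_t2_signals(np.array([10.0, 5.0]), (10, 20))

    def test_drop_first_echo_noiseless_equivalent(self):
        sig = simulate_signal(40.0, 100.0, TE)
        t2, _, valid = fit_t2_signals(sig, TE, drop_first_echo=True)
        assert valid[0] and t2[0] == pytest.approx(40.0, rel=1e-6)

    def test_fit_t2_masked_volume(self):
        data = np.zeros((7, 2, 4, 4))
        data[:, 0, 0, 0] = simulate_signal(55.0, 90.0, TE)
        data[:, 1, 3, 3] = simulate_signal(25.0, 120.0, TE)
        vol = MESEVolume(data, SPACING, TE)
        labels = np.zeros((2, 4, 4), dtype=np.int16)
        labels[0, 0, 0] = labels[1, 3, 3] = 1
        fitted = fit_t2(vol, LabelMask(labels, {"c": 1}, SPACING))
        assert fitted.valid[0, 0, 0] and fitted.valid[1, 3, 3]
        assert fitted.t2_ms[0, 0, 0] == pytest.approx(55.0, rel=1e-6)
        assert fitted.t2_ms[1, 3, 3] == pytest.approx(25.0, rel=1e-6)
        assert not fitted.valid[0, 1, 1]  # outside mask


def _mask(arr, spacing=SPACING, name="x"):
    return LabelMask(arr.astype(np.int16), {name: 1}, spacing)


class TestDepth:
    def test_symmetric_slab_split(self):
        """An 8-row cartilage slab on bone: the 4 bone-side rows are deep."""
        cart = np.zeros((1, 16, 8), dtype=int)
        bone = np.zeros((1, 16, 8), dtype=int)
        cart[0, 2:10, :] = 1      # rows 2..9, surface at row 2
        bone[0, 10:13, :] = 1     # bone below
        depth = compute_depth(_mask(cart), _mask(bone))
        for r in range(2, 10):
            frac = depth[0, r, 4]
            if r >= 6:   # bone-side half
                assert frac < 0.5
            else:
                assert frac >= 0.5

    def test_single_voxel_thick_is_half(self):
        cart = np.zeros((1, 8, 8), dtype=int)
        bone = np.zeros((1, 8, 8), dtype=int)
        cart[0, 3, :] = 1
        bone[0, 4, :] = 1
        depth = compute_depth(_mask(cart), _mask(bone))
        np.testing.assert_allclose(depth[0, 3, :], 0.5)

    def test_component_without_bone_flagged_nan(self):
        cart = np.zeros((1, 8, 8), dtype=int)
        bone = np.zeros((1, 8, 8), dtype=int)
        cart[0, 1:3, 1:3] = 1     # floating island, no bone anywhere
        depth = compute_depth(_mask(cart), _mask(bone))
        assert np.isnan(depth[0, 1:3, 1:3]).all()

    def test_curved_annulus_deep_fraction_near_half(self):
        """Ring of cartilage around a bone disk: the depth-based deep
        fraction stays within 0.05 of the voxel-counting oracle (0.5)."""
        n = 64
        yy, xx = np.mgrid[:n, :n]
        r = np.hypot(yy - n / 2, xx - n / 2)
        bone = np.zeros((1, n, n), dtype=int)
        cart = np.zeros((1, n, n), dtype=int)
        bone[0][r < 14] = 1
        cart[0][(r >= 14) & (r < 22)] = 1
        depth = compute_depth(_mask(cart, (3.5, 1, 1)), _mask(bone, (3.5, 1, 1)))
        sel = cart[0] > 0
        deep_fraction = (depth[0][sel] < 0.5).mean()
        # voxel-counting oracle: deep voxels are those inside the mid-radius
        oracle = (r[sel] < (14 + 22) / 2).mean()
        assert abs(deep_fraction - oracle) <= 0.05

    def test_disjointness_required(self):
        arr = np.zeros((1, 4, 4), dtype=int)
        arr[0, 1, 1] = 1
        with pytest.raises(ValueError):
            compute_depth(_mask(arr), _mask(arr))


class TestPartition:
    def test_even_slab_exact_split(self, noiseless_phantom):
        _, truth = noiseless_phantom
        depth = compute_depth(
            _mask((truth.cartilage_mask.labels > 0).astype(int),
                  truth.cartilage_mask.spacing_mm),
            truth.bone_mask)
        part = partition_layers(depth)
        cart = truth.cartilage_mask.labels > 0
        assert (part.layer[cart] > 0).all()
        assert (part.layer == LAYER_DEEP).sum() == (part.layer == LAYER_SUPERFICIAL).sum()

    def test_all_zero_depth_all_deep(self):
        part = partition_layers(np.zeros((2, 3, 3)))
        assert (part.layer == LAYER_DEEP).all()

    def test_threshold_matches_bruteforce_oracle(self, rng):
        d = rng.uniform(0, 1, size=(3, 8, 8))
        d[0, 0, 0] = 0.5  # tie goes superficial
        part = partition_layers(d)
        expected_sup = sum(
            1 for v in d.ravel() if v >= 0.5)
        assert (part.layer == LAYER_SUPERFICIAL).sum() == expected_sup
        assert part.layer[0, 0, 0] == LAYER_SUPERFICIAL

    def test_nan_depth_unassigned(self):
        d = np.array([[[np.nan, 0.2]]])
        part = partition_layers(d)
        assert part.layer[0, 0, 0] == 0
        assert part.layer[0, 0, 1] == LAYER_DEEP


class TestAggregate:
    def test_printed_deep_plate_means_reproduce_compartments(self):
        reg = RegionalT2.from_plate_means({
            ("MT", "deep"): 33.5, ("cMF", "deep"): 41.9,
            ("LT", "deep"): 32.4, ("cLF", "deep"): 41.0,
            ("MT", "superficial"): 43.5, ("cMF", "superficial"): 51.7,
            ("LT", "superficial"): 44.0, ("cLF", "superficial"): 49.4,
        })
        assert reg.mean("FTJ", "deep") == pytest.approx(37.2, abs=1e-9)
        assert reg.mean("MFTC", "deep") == pytest.approx(37.7, abs=1e-9)
        assert reg.mean("LFTC", "deep") == pytest.approx(36.7, abs=1e-9)
        assert reg.mean("FTJ", "superficial") == pytest.approx(47.15, abs=1e-9)

    def test_constant_field_constant_aggregates(self):
        reg = RegionalT2.from_plate_means(
            {(p, l): 42.0 for p in t2map.PLATES for l in t2map.LAYERS})
        for region in ("MT", "cMF", "LT", "cLF", "MFTC", "LFTC", "FTJ"):
            for layer in t2map.LAYERS:
                assert reg.mean(region, layer) == 42.0

    def _small_setup(self):
        shape = (2, 4, 4)
        labels = np.zeros(shape, dtype=np.int16)
        labels[0, :2, :] = 1   # MT
        labels[0, 2:, :] = 2   # cMF
        labels[1, :2, :] = 3   # LT
        labels[1, 2:, :] = 4   # cLF
        plates = LabelMask(labels, {"MT": 1, "cMF": 2, "LT": 3, "cLF": 4}, SPACING)
        layer = np.where(np.arange(4)[None, :, None] % 2 == 0,
                         LAYER_DEEP, LAYER_SUPERFICIAL) * (labels > 0)
        part = LayerPartition(layer=layer.astype(np.int8), depth_fraction=None)
        t2 = T2Map(t2_ms=np.full(shape, 40.0), s0=np.full(shape, 100.0),
                   valid=labels > 0)
        return t2, part, plates

    def test_conservation_per_plate(self):
        t2, part, plates = self._small_setup()
        reg = aggregate(t2, part, plates)
        for plate in t2map.PLATES:
            total = (plates.binary(plate)).sum()
            assert reg.n(plate, "deep") + reg.n(plate, "superficial") == total

    def test_superficial_shift_moves_only_superficial(self):
        t2, part, plates = self._small_setup()
        base = aggregate(t2, part, plates)
        delta = 2.5
        shifted = T2Map(
            t2_ms=t2.t2_ms + delta * (part.layer == LAYER_SUPERFICIAL),
            s0=t2.s0, valid=t2.valid)
        moved = aggregate(shifted, part, plates)
        for region in ("MT", "cMF", "LT", "cLF", "MFTC", "LFTC", "FTJ"):
            assert moved.mean(region, "superficial") == pytest.approx(
                base.mean(region, "superficial") + delta, abs=1e-9)
            assert moved.mean(region, "deep") == pytest.approx(
                base.mean(region, "deep"), abs=1e-9)

    def test_ftj_identity(self):
        t2, part, plates = self._small_setup()
        t2.t2_ms[plates.binary("MT")] = 33.0
        t2.t2_ms[plates.binary("cLF")] = 51.0
        reg = aggregate(t2, part, plates)
        for layer in t2map.LAYERS:
            plate_mean = np.mean([reg.mean(p, layer) for p in t2map.PLATES])
            assert reg.mean("FTJ", layer) == pytest.approx(plate_mean, abs=1e-9)

    def test_empty_cell_is_nan_not_zero(self):
        t2, part, plates = self._small_setup()
        t2.valid[plates.binary("MT")] = False
        reg = aggregate(t2, part, plates)
        assert np.isnan(reg.mean("MT", "deep"))
        assert reg.n("MT", "deep") == 0
        assert np.isnan(reg.mean("FTJ", "deep"))


class TestPhantomRecoveryUnderNoise:
    def test_layer_means_within_1ms(self, noisy_phantom):
        """With true layer T2 (38, 48) and sigma=3, the full laminar pipeline
        on true masks recovers layer means within +/-1 ms."""
        vol, truth = noisy_phantom
        from lamt2.pipeline import run_case

        reg, _ = run_case(vol, truth.bone_mask, truth.cartilage_binary_mask())
        assert reg.mean("FTJ", "deep") == pytest.approx(38.0, abs=1.0)
        assert reg.mean("FTJ", "superficial") == pytest.approx(48.0, abs=1.0)
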