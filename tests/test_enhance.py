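import numpy as np
import pytest

from lettucevision import enhance as en


class TestGlobalEqualize:
    def test_constant_plane_maps_to_white(self):
        plane = np.full((16, 16), 37, np.uint8)
        assert (en.global_equalize(plane) == 255).all()

    def test_two_level_plane(self):
        plane = np.full((16, 16), 10, np.uint8)
        plane[:8] = 200  # half 10, half 200
        out = en.global_equalize(plane)
        assert set(np.unique(out[plane == 10])) == {128}  # round-half-up of 127.5
        assert set(np.unique(out[plane == 200])) == {255}

    def test_uniform_plane_near_identity(self):
        plane = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = en.global_equalize(plane)
        assert np.abs(out.astype(int) - plane.astype(int)).max() <= 1

    def test_mapping_monotone(self, rng):
        plane = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        lut = en.equalize_map(plane)
        assert (np.diff(lut.astype(int)) >= 0).all()

    def test_near_idempotence(self, rng):
        plane = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        once = en.global_equalize(plane)
        lut2 = en.equalize_map(once)
        # re-equalizing moves present levels by at most one
        present = np.unique(once)
        assert np.abs(lut2[present].astype(int) - present.astype(int)).max() <= 1


class TestClipLimit:
    def test_bright_tile_keeps_base(self):
        assert en.adjust_clip_limit(200.0, 4.0, 0.1, 128.0) == 4.0

    def test_dark_tile_raises_limit(self):
        assert en.adjust_clip_limit(28.0, 4.0, 0.1, 128.0) == pytest.approx(14.0)

    def test_zero_scale_degenerates_to_base(self):
        assert en.adjust_clip_limit(0.0, 4.0, 0.0, 128.0) == 4.0

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            en.adjust_clip_limit(100.0, 0.0, 0.1, 128.0)


class TestClipAndRedistribute:
    def test_no_excess_is_identity(self):
        h = np.full(256, 3, np.int64)
        assert np.array_equal(en.clip_and_redistribute(h, 10, 0.05, 3.0), h)

    def test_sigmoid_midpoint_spreads_uniformly(self):
        h = np.full(256, 10, np.int64)
        h[0] = 522  # spike of 522, excess 512 over clip 10 -> 2 per bin
        out = en.clip_and_redistribute(h, 10, 0.05, 10.0)
        assert out.sum() == h.sum()
        # all non-spike bins sit at the sigmoid midpoint -> equal weights
        assert np.ptp(out[1:]) <= 1

    def test_single_spike_conservation(self):
        h = np.zeros(256, np.int64)
        h[40] = 100
        out = en.clip_and_redistribute(h, 10, 0.05, float(h.mean()))
        assert out.sum() == 100
        assert np.minimum(h, 10)[40] == 10  # clip bound held before redistribution

    @pytest.mark.parametrize("invert", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conservation_and_clip_bound_random(self, seed, invert):
        r = np.random.default_rng(seed)
        h = r.integers(0, 50, 256).astype(np.int64)
        clip = 12
        out = en.clip_and_redistribute(h, clip, 0.05, float(h.mean()), invert)
        assert out.sum() == h.sum()  # pixel conservation, exact
        assert (np.minimum(h, clip) <= clip).all()
        assert (out >= np.minimum(h, clip)).all()

    def test_invalid_clip_rejected(self):
        with pytest.raises(ValueError):
            en.clip_and_redistribute(np.ones(256, np.int64), 0.5, 0.05, 1.0)


class TestTileRemap:
    def test_constant_tile_identity(self):
        tile = np.full((8, 8), 99, np.uint8)
        h = np.bincount(tile.ravel(), minlength=256)
        assert np.array_equal(en.tile_remap(h, tile), tile)

    def test_uniform_histogram_near_identity(self):
        tile = np.arange(256, dtype=np.uint8).reshape(16, 16)
        h = np.bincount(tile.ravel(), minlength=256)
        out = en.tile_remap(h, tile)
        assert np.abs(out.astype(int) - tile.astype(int)).max() <= 1

    def test_lower_half_stretched_to_full_range(self):
        tile = np.repeat(np.arange(0, 128, dtype=np.uint8), 2).reshape(16, 16)
        h = np.bincount(tile.ravel(), minlength=256)
        out = en.tile_remap(h, tile)
        assert out.max() == 255 and out.min() == 0

    def test_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            en.tile_remap(np.zeros(256, np.int64), np.zeros((4, 4), np.uint8))


class TestBicubicKernel:
    def test_kernel_table_structure(self):
        w = en.bicubic_kernel_weights()
        assert w.shape == (5, 5)
        assert w.sum() == pytest.approx(1.0)
        assert w[2, 2] == w.max()
        assert np.allclose(w[0], 0) and np.allclose(w[:, 0], 0)  # K vanishes at |u|=1

    def test_center_spike_blend(self):
        # 5×5 patch, center 100: output = 100·Wnorm(0,0) with
        # Wnorm(0,0) = 1/(1+2·(15/16))² = 0.120983 -> rounds to 12
        patch = np.zeros((5, 5), np.float64)
        patch[2, 2] = 100.0
        w = en.bicubic_kernel_weights()
        assert 100.0 * w[2, 2] == pytest.approx(12.0983, abs=1e-3)
        out = en.bicubic_reconstruct(patch)
        assert out[2, 2] == 12

    def test_constant_region_unchanged(self):
        patch = np.full((9, 9), 150, np.uint8)
        assert np.array_equal(en.bicubic_reconstruct(patch), patch)


class TestImprovedClahe:
    def test_constant_image_stays_constant(self):
        plane = np.full((64, 64), 90, np.uint8)
        out = en.improved_clahe(plane)
        assert np.ptp(out) == 0

    def test_output_in_range(self, rng):
        for _ in range(10):
            plane = rng.integers(0, 256, (64, 64), dtype=np.uint8)
            out = en.improved_clahe(plane)
            assert out.dtype == np.uint8  # uint8 guarantees [0, 255]

    def test_low_contrast_canopy_tile_spread_increases(self):
        # a canopy scene with its V dynamic range compressed to ~1/4:
        # tile-local brightness spread must not shrink, and grows on average
        from lettucevision import raster_core as rc
        from lettucevision.synthdata import SceneSpec, generate_scene

        img, _ = generate_scene(
            SceneSpec(lesion_class="N", lesion_fraction=0.15,
                      noise_density=0.0, seed=3)
        )
        v = rc.rgb_to_hsv(img)[:, :, 2]
        low = np.clip(np.floor(v * 0.25 + 96 + 0.5), 0, 255).astype(np.uint8)
        out = en.improved_clahe(low)
        edges = np.linspace(0, low.shape[0], 9).astype(int)
        stds_in, stds_out = [], []
        for i in range(8):
            for j in range(8):
                sl = np.s_[edges[i] : edges[i + 1], edges[j] : edges[j + 1]]
                stds_in.append(low[sl].astype(float).std())
                stds_out.append(out[sl].astype(float).std())
        assert np.mean(stds_out) > np.mean(stds_in)
        # no tile loses more than a seam-blending sliver of spread
        assert (np.array(stds_out) >= np.array(stds_in) - 0.7).all()

    def test_tiny_tiles_rejected(self):
        with pytest.raises(ValueError):
            en.improved_clahe(np.zeros((7, 64), np.uint8))


class TestFusion:
    def test_midpoint_alpha_half(self):
        p = en.FusionParams()
        assert en.fusion_weight(p.l0, p.sigma0, p) == pytest.approx(0.5)
        zg = np.full((8, 8), 100, np.uint8)
        zl = np.full((8, 8), 200, np.uint8)
        z, alpha = en.fuse_global_local(zg, zl, p.l0, p.sigma0, p)
        assert alpha == pytest.approx(0.5)
        assert (z == 150).all()

    def test_hand_computed_sigmoid(self):
        p = en.FusionParams(k=0.05, m=0.05, l0=100.0, sigma0=60.0)
        # L_avg−L0 = 20, σ−σ0 = −10 -> z = 0.5 -> α ≈ 0.6225
        assert en.fusion_weight(120.0, 50.0, p) == pytest.approx(0.62246, abs=1e-4)

    def test_saturation_limit(self):
        p = en.FusionParams(k=50.0, m=50.0)
        zg = np.full((4, 4), 30, np.uint8)
        zl = np.full((4, 4), 220, np.uint8)
        z, alpha = en.fuse_global_local(zg, zl, p.l0 + 10, p.sigma0, p)
        assert alpha > 0.999999
        assert (z == 30).all()

    def test_convexity_and_open_interval(self, rng):
        p = en.FusionParams()
        for _ in range(10):
            zg = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            zl = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            l_avg, sigma = rng.uniform(0, 255), rng.uniform(0, 120)
            z, alpha = en.fuse_global_local(zg, zl, l_avg, sigma, p)
            assert 0.0 < alpha < 1.0
            lo = np.minimum(zg, zl)
            hi = np.maximum(zg, zl)
            assert (z >= lo).all() and (z <= hi).all()

    def test_clgce_runs_and_preserves_dtype(self, rng):
        plane = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        out = en.clgce(plane)
        assert out.shape == plane.shape and out.dtype == np.uint8
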