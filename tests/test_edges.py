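import numpy as np
import pytest

from lettucevision import edges as ed
from lettucevision import denoise as dn
from lettucevision.synthdata import add_impulse_noise

from .oracles import brute_hysteresis, brute_nms, brute_percentile_95


def disk_image(size=64, radius=20, fg=200, bg=30):
    yy, xx = np.indices((size, size))
    c = (size - 1) / 2
    img = np.full((size, size), bg, np.float64)
    img[np.hypot(yy - c, xx - c) <= radius] = fg
    return img


class TestKernelBank:
    def test_zero_sum_and_antisymmetry(self):
        bank = ed.kernel_bank()
        assert set(bank) == set(ed.KERNEL_ANGLES)
        for angle, k in bank.items():
            assert k.sum() == 0, angle
            assert np.array_equal(bank[(angle + 180) % 360], -k), angle


class TestDirectionalGradients:
    def test_constant_plane_all_zero(self):
        field = ed.directional_gradients(np.full((10, 10), 80.0))
        for g in field.values():
            assert np.allclose(g, 0)

    def test_vertical_step_dominated_by_horizontal_kernel(self):
        plane = np.zeros((10, 10))
        plane[:, 5:] = 255.0
        field = ed.directional_gradients(plane)
        edge_col = 4
        assert np.abs(field[0][:, edge_col]).max() >= np.abs(field[90][:, edge_col]).max()
        assert np.allclose(field[90][:, edge_col], 0)  # rows are constant

    def test_opposite_kernels_negate(self, rng):
        plane = rng.uniform(0, 255, (12, 12))
        field = ed.directional_gradients(plane)
        assert np.allclose(field[180], -field[0])
        assert np.allclose(field[315], -field[135])


class TestCombineGradients:
    def test_zero_field(self):
        field = {a: np.zeros((5, 5)) for a in ed.KERNEL_ANGLES}
        g, theta = ed.combine_gradients(field)
        assert (g == 0).all() and (theta == 0).all()

    def test_paired_energy_doubles(self):
        field = {a: np.zeros((3, 3)) for a in ed.KERNEL_ANGLES}
        field[0] = np.full((3, 3), 3.0)
        field[180] = np.full((3, 3), -3.0)
        g, _ = ed.combine_gradients(field)
        assert np.allclose(g, np.sqrt(18.0))

    def test_sqrt2_identity_and_atan2_oracle(self, rng):
        plane = rng.uniform(0, 255, (32, 32))
        field = ed.directional_gradients(plane)
        g, theta = ed.combine_gradients(field)
        four = np.sqrt(sum(field[a] ** 2 for a in (0, 45, 90, 135)))
        assert np.abs(g - np.sqrt(2.0) * four).max() < 1e-9
        rad = np.deg2rad(ed.KERNEL_ANGLES)
        sy = sum(field[a] * np.sin(r) for a, r in zip(ed.KERNEL_ANGLES, rad))
        sx = sum(field[a] * np.cos(r) for a, r in zip(ed.KERNEL_ANGLES, rad))
        expect = np.arctan2(sy, sx)
        nz = g > 1e-12
        assert np.allclose(theta[nz], expect[nz])


class TestNms:
    def test_isolated_peak_kept(self):
        mag = np.zeros((5, 5))
        mag[2, 2] = 10.0
        out = ed.nms_interpolated(mag, np.zeros((5, 5)))
        assert out[2, 2] == 10.0

    def test_plateau_all_kept(self):
        mag = np.full((6, 6), 4.0)
        out = ed.nms_interpolated(mag, np.full((6, 6), 0.3))
        assert (out == 4.0).all()  # ties use ≥

    def test_exact_45_degrees_compares_diagonals(self):
        mag = np.zeros((3, 3))
        mag[1, 1] = 5.0
        mag[0, 2] = 7.0  # a2 beats the center along the 45° line
        theta = np.full((3, 3), np.deg2rad(45.0))
        out = ed.nms_interpolated(mag, theta)
        assert out[1, 1] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_per_pixel_oracle(self, seed):
        r = np.random.default_rng(seed)
        mag = r.uniform(0, 100, (20, 20))
        theta = r.uniform(-np.pi, np.pi, (20, 20))
        assert np.array_equal(ed.nms_interpolated(mag, theta), brute_nms(mag, theta))


class TestAutoThresholds:
    def test_nearest_rank_on_1_to_100(self):
        mags = np.arange(0, 101, dtype=float)  # zero excluded from the rank
        thr = ed.auto_thresholds(mags, ratio=0.4)
        assert thr.high == brute_percentile_95(mags) == 95.0
        assert thr.low == pytest.approx(38.0)

    def test_degenerate_constant_distribution(self):
        thr = ed.auto_thresholds(np.full((8, 8), 7.5), ratio=0.5)
        assert thr.high == 7.5 and thr.low == pytest.approx(3.75)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ed.auto_thresholds(np.zeros((8, 8)))

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            ed.auto_thresholds(np.ones((4, 4)), ratio=1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_fields_match_sort_oracle(self, seed):
        r = np.random.default_rng(seed)
        mags = r.exponential(10, (40, 40)) * (r.random((40, 40)) > 0.3)
        thr = ed.auto_thresholds(mags)
        assert thr.high == brute_percentile_95(mags)
        # at most 5% of nonzero pixels exceed T_high
        nz = mags[mags > 0]
        assert (nz > thr.high).sum() <= 0.05 * nz.size


class TestHysteresis:
    def test_no_strong_gives_empty(self):
        supp = np.full((6, 6), 5.0)
        assert not ed.hysteresis_link(supp, 10.0, 2.0).any()

    def test_diagonal_weak_neighbor_kept(self):
        supp = np.zeros((5, 5))
        supp[2, 2] = 20.0  # strong
        supp[3, 3] = 6.0  # weak, diagonal
        out = ed.hysteresis_link(supp, 10.0, 5.0)
        assert out[2, 2] and out[3, 3]

    def test_chain_with_gap(self):
        supp = np.zeros((1, 7))
        supp[0, :3] = [20.0, 6.0, 6.0]  # strong, weak, weak
        supp[0, 4] = 6.0  # weak after the gap
        out = ed.hysteresis_link(supp, 10.0, 5.0)
        assert out[0, 0] and out[0, 1] and out[0, 2]
        assert not out[0, 3] and not out[0, 4]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        supp = r.uniform(0, 30, (24, 24)) * (r.random((24, 24)) > 0.4)
        out = ed.hysteresis_link(supp, 20.0, 8.0)
        assert np.array_equal(out, brute_hysteresis(supp, 20.0, 8.0))


class TestImprovedCanny:
    def test_constant_image_empty_map(self):
        assert not ed.improved_canny(np.full((32, 32), 120.0)).any()

    def test_disk_yields_closed_thin_ring(self):
        img = disk_image()
        edge = ed.improved_canny(img, ratio=0.4, sigma_blur=1.0)
        yy, xx = np.nonzero(edge)
        c = (img.shape[0] - 1) / 2
        rr = np.hypot(yy - c, xx - c)
        assert edge.sum() > 0
        assert rr.min() > 15 and rr.max() < 25  # ring near radius 20
        # closed ring: edge pixels in every angular octant
        ang = np.degrees(np.arctan2(yy - c, xx - c)) % 360
        assert len(np.unique((ang // 45).astype(int))) == 8

    def test_noise_robust_edge_count_after_denoise(self):
        img = disk_image().astype(np.uint8)
        clean_count = ed.improved_canny(img.astype(float)).sum()
        noisy = add_impulse_noise(np.stack([img] * 3, -1), 0.02, seed=5)
        den = dn.dynamic_median_filter(noisy)[:, :, 0]
        noisy_count = ed.improved_canny(den.astype(float)).sum()
        assert abs(noisy_count - clean_count) <= 0.10 * clean_count
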