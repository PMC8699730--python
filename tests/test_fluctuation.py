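"""Mask construction, temporal std, radial averaging and the fluctuation map."""

import numpy as np
import pytest

from phasefluct.fluctuation import (CellMask, build_mask, classifier_map,
                                    fluctuation_map, radial_average,
                                    temporal_std_map)
from phasefluct.holography import OPDVideo


def disk_mask(n: int, radius: float) -> CellMask:
    yy, xx = np.mgrid[:n, :n]
    return CellMask(np.hypot(yy - n // 2, xx - n // 2) <= radius)


class TestBuildMask:
    def test_disk_from_flat_topped_cell(self):
        # support is exactly a disk of radius 80 -> analysis disk ~ 0.7 * 80
        yy, xx = np.mgrid[:200, :200]
        frame = np.where(np.hypot(yy - 100, xx - 100) <= 80, 100.0, 0.0)
        mask = build_mask(frame, threshold_frac=0.2, erode_frac=0.7)
        assert mask.radius_px == pytest.approx(0.7 * 80, rel=0.02)
        assert mask.center[0] == pytest.approx(100, abs=1)
        assert mask.center[1] == pytest.approx(100, abs=1)

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError, match="no cell detected"):
            build_mask(np.zeros((64, 64)))

    def test_mask_pixels_lie_on_cell(self):
        yy, xx = np.mgrid[:128, :128]
        r2 = ((yy - 64) ** 2 + (xx - 64) ** 2) / 40.0 ** 2
        dome = 300.0 * np.clip(1 - r2, 0, None)
        mask = build_mask(dome, threshold_frac=0.2, erode_frac=0.7)
        assert np.all(dome[mask.pixels] > 0.2 * dome.max())

    def test_tiny_cell_rejected(self):
        frame = np.zeros((64, 64))
        frame[30:33, 30:33] = 1.0
        with pytest.raises(ValueError):
            build_mask(frame)

    def test_mask_invariants_enforced(self):
        border = np.ones((32, 32), dtype=bool)
        with pytest.raises(ValueError, match="border"):
            CellMask(border)
        with pytest.raises(ValueError, match="pixels"):
            CellMask(np.pad(np.ones((5, 5), bool), 10))


class TestTemporalStd:
    def test_static_video_gives_zero(self):
        video = OPDVideo(np.tile(np.random.default_rng(0).random((16, 16)), (8, 1, 1)), 500.0)
        out = temporal_std_map(video, disk_mask(16, 6))
        assert np.allclose(out.values, 0.0)

    def test_alternating_pixel_closed_form(self):
        t, a = 16, 3.7
        frames = np.zeros((t, 16, 16))
        frames[:, 8, 8] = a * (-1.0) ** np.arange(t)
        out = temporal_std_map(OPDVideo(frames, 500.0), disk_mask(16, 6))
        assert out.values[8, 8] == pytest.approx(a * np.sqrt(t / (t - 1)))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        frames = rng.random((16, 16, 16))
        mask = CellMask(np.pad(np.ones((11, 11), bool), ((3, 2), (2, 3))))
        out = temporal_std_map(OPDVideo(frames, 1.0), mask).values
        for y in range(16):
            for x in range(16):
                if mask.pixels[y, x]:
                    v = frames[:, y, x]
                    exp = np.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - 1))
                    assert out[y, x] == pytest.approx(exp, rel=1e-10)
                else:
                    assert out[y, x] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            temporal_std_map(OPDVideo(np.zeros((4, 8, 8)), 1.0), disk_mask(16, 6))


def brute_force_radial_average(plane, n_bins):
    h, w = plane.shape
    r_max = max(np.hypot(y - h // 2, x - w // 2)
                for y in range(h) for x in range(w))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for y in range(h):
        for x in range(w):
            r = np.hypot(y - h // 2, x - w // 2)
            b = min(int(r / r_max * n_bins), n_bins - 1) if r_max > 0 else 0
            sums[b] += plane[y, x]
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


class TestRadialAverage:
    def test_constant_plane(self):
        out = radial_average(np.full((9, 9), 4.2), 4)
        assert np.allclose(out[~np.isnan(out)], 4.2)

    def test_single_pixel_localized(self):
        plane = np.zeros((17, 17))
        plane[8, 12] = 5.0  # radius 4
        out = radial_average(plane, 8)
        r_max = np.hypot(8, 8)
        b = int(4 / r_max * 8)
        nonzero = np.nonzero(np.nan_to_num(out))[0]
        assert list(nonzero) == [b]

    @pytest.mark.parametrize("seed,shape,n_bins", [(0, (9, 9), 4), (1, (12, 7), 5),
                                                   (2, (16, 16), 8)])
    def test_matches_brute_force(self, seed, shape, n_bins):
        plane = np.random.default_rng(seed).random(shape)
        exp, _ = brute_force_radial_average(plane, n_bins)
        got = radial_average(plane, n_bins)
        assert np.allclose(got, exp, rtol=1e-12, equal_nan=True)

    def test_count_weighted_mass_conservation(self):
        plane = np.random.default_rng(3).random((15, 15))
        means, counts = radial_average(plane, 6, return_counts=True)
        total = np.nansum(np.nan_to_num(means) * counts)
        assert total == pytest.approx(plane.sum(), rel=1e-9)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            radial_average(np.ones((4, 4)), 0)


class TestFluctuationMap:
    def test_static_video_zero_map(self):
        frame = np.random.default_rng(0).random((32, 32))
        video = OPDVideo(np.tile(frame, (8, 1, 1)), 500.0)
        fmap = fluctuation_map(video, disk_mask(32, 12))
        assert np.allclose(fmap.power, 0.0, atol=1e-18)

    def test_traveling_wave_localized(self):
        t = h = w = 32
        mask = disk_mask(32, 14)
        tt = np.arange(t)[:, None, None]
        xx = np.mgrid[:h, :w][1][None]
        k0, m0 = 7, 5
        wave = np.cos(2 * np.pi * (k0 * xx / w - m0 * tt / t))
        video = OPDVideo(wave * mask.pixels[None], 500.0)
        fmap = fluctuation_map(video, mask, n_bins=8)
        i, j = np.unravel_index(np.nanargmax(fmap.power), fmap.power.shape)
        assert i == m0 - 1  # omega rows start at the first nonzero frequency
        assert j == int(k0 / np.hypot(16, 16) * 8)
        rest = fmap.power.copy()
        rest[i, j] = np.nan
        assert fmap.power[i, j] > 10 * np.nanmax(rest)

    def test_static_offset_invariance(self):
        rng = np.random.default_rng(2)
        frames = rng.random((8, 16, 16))
        mask = disk_mask(16, 6)
        base = fluctuation_map(OPDVideo(frames, 500.0), mask)
        offset = fluctuation_map(OPDVideo(frames + rng.random((16, 16))[None], 500.0), mask)
        assert np.allclose(base.power, offset.power, rtol=1e-9, atol=1e-12)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(4)
        frames = rng.random((8, 16, 16))
        mask = disk_mask(16, 6)
        p1 = fluctuation_map(OPDVideo(frames, 500.0), mask).power
        p3 = fluctuation_map(OPDVideo(3.0 * frames, 500.0), mask).power
        assert np.allclose(p3, 9.0 * p1, rtol=1e-9)

    def test_parseval_energy_bookkeeping(self):
        rng = np.random.default_rng(5)
        video = OPDVideo(rng.standard_normal((16, 16, 16)), 1.0)
        _, energy = fluctuation_map(video, disk_mask(16, 6), return_energy=True)
        assert energy["total_power"] == pytest.approx(
            energy["n_total"] * energy["signal_energy"], rel=1e-9)

    def test_axes_shapes_and_order(self):
        rng = np.random.default_rng(6)
        video = OPDVideo(rng.standard_normal((16, 20, 20)), 500.0)
        fmap = fluctuation_map(video, disk_mask(20, 8))
        assert fmap.power.shape == (8, fmap.q_axis.size)
        assert np.all(np.diff(fmap.omega_axis) > 0)
        assert np.all(np.diff(fmap.q_axis) > 0)
        assert fmap.omega_axis[-1] == pytest.approx(250.0)  # Nyquist of 500 Hz

    def test_white_noise_spectrum_is_flat(self):
        # bin-averaged power over many realizations has no q or omega trend
        rng = np.random.default_rng(42)
        mask = CellMask(np.pad(np.ones((12, 12), bool), 2))
        acc, acc2, n_real = None, None, 200
        for _ in range(n_real):
            p = fluctuation_map(OPDVideo(rng.standard_normal((16, 16, 16)), 1.0),
                                mask).power
            acc = p if acc is None else acc + p
            acc2 = p ** 2 if acc2 is None else acc2 + p ** 2
        mean_map = acc / n_real
        se = np.sqrt((acc2 / n_real - mean_map ** 2) / (n_real - 1))
        grand = np.nanmean(mean_map)
        assert np.nanmax(np.abs(mean_map - grand) / se) < 3.0

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fluctuation_map(OPDVideo(np.zeros((3, 16, 16)), 1.0), disk_mask(16, 6))


def test_classifier_map_range_and_size():
    rng = np.random.default_rng(0)
    video = OPDVideo(rng.standard_normal((16, 32, 32)), 500.0)
    fmap = fluctuation_map(video, disk_mask(32, 12))
    img = classifier_map(fmap, size=16)
    assert img.shape == (16, 16)
    assert img.min() >= 0.0 and img.max() <= 1.0
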