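"""Slice-image quantification: masks, fractions, viability, nuclei."""

import numpy as np
import pytest

from slicequant import imaging as im
from slicequant.synth import synth_timelapse


def _disk_image(size=256, radius=100, fg=1.0, bg=0.0):
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return np.where(mask, fg, bg), mask


class TestSegmentTissue:
    def test_disk_area_matches_pi_r_squared(self):
        img, _ = _disk_image(radius=100)
        _, area = im.segment_tissue(img, pixel_size_um=10.0)
        assert area == pytest.approx(np.pi * 1.0**2, rel=0.02)  # r = 1 mm

    def test_area_scales_with_pixel_size_squared(self):
        img, _ = _disk_image(radius=60)
        _, a1 = im.segment_tissue(img, pixel_size_um=10.0)
        _, a2 = im.segment_tissue(img, pixel_size_um=20.0)
        assert a2 == pytest.approx(4.0 * a1)

    def test_idempotent_on_own_mask(self):
        img, _ = _disk_image(radius=80)
        mask, area = im.segment_tissue(img, pixel_size_um=10.0)
        _, area2 = im.segment_tissue(mask.astype(float), pixel_size_um=10.0)
        assert area2 == pytest.approx(area)

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="no tissue"):
            im.segment_tissue(np.zeros((64, 64)), pixel_size_um=10.0)


class TestChannelMask:
    def test_otsu_separates_bimodal_modes(self):
        rng = np.random.default_rng(0)
        tissue = np.ones((64, 64), dtype=bool)
        img = rng.normal(0.2, 0.02, (64, 64))
        img[:, 32:] = rng.normal(0.8, 0.02, (64, 32))
        mask = im.channel_mask(img, tissue, method="otsu")
        assert mask[:, 32:].mean() > 0.99
        assert mask[:, :32].mean() < 0.01

    def test_all_zero_channel_gives_empty_mask(self):
        tissue = np.ones((16, 16), dtype=bool)
        assert not im.channel_mask(np.zeros((16, 16)), tissue).any()

    def test_fixed_zero_threshold_gives_full_tissue(self):
        tissue = np.zeros((16, 16), dtype=bool)
        tissue[4:12, 4:12] = True
        img = np.random.default_rng(1).random((16, 16))
        mask = im.channel_mask(img, tissue, method="fixed", threshold=0.0)
        assert (mask == tissue).all()

    def test_fixed_threshold_outside_range_rejected(self):
        tissue = np.ones((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="outside"):
            im.channel_mask(np.zeros((8, 8)), tissue, method="fixed", threshold=2.0)


class TestAreaFractions:
    def test_brute_force_pixel_count(self):
        tissue = np.ones((10, 10), dtype=bool)
        red = np.zeros_like(tissue)
        green = np.zeros_like(tissue)
        red.ravel()[:20] = True
        green.ravel()[16:26] = True  # 4 px overlap with red
        r, g, y = im.area_fractions(red, green, tissue)
        assert (r, g, y) == (20.0, 10.0, 4.0)

    def test_no_green_means_no_yellow(self):
        tissue = np.ones((10, 10), dtype=bool)
        red = tissue.copy()
        r, g, y = im.area_fractions(red, np.zeros_like(tissue), tissue)
        assert g == 0.0 and y == 0.0

    def test_yellow_bounded_by_red_and_green(self):
        rng = np.random.default_rng(2)
        tissue = np.ones((32, 32), dtype=bool)
        red = rng.random((32, 32)) > 0.5
        green = rng.random((32, 32)) > 0.7
        r, g, y = im.area_fractions(red, green, tissue)
        assert y <= min(r, g)

    def test_empty_tissue_rejected(self):
        empty = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            im.area_fractions(empty, empty, empty)


class TestViability:
    def test_arithmetic(self):
        live = np.zeros((20, 20), dtype=bool)
        dead = np.zeros((20, 20), dtype=bool)
        live.ravel()[:300] = True
        dead.ravel()[300:400] = True
        assert im.viability(live, dead) == pytest.approx(75.0)

    def test_no_dead_signal_is_fully_viable(self):
        live = np.ones((8, 8), dtype=bool)
        assert im.viability(live, np.zeros_like(live)) == 100.0

    def test_killed_control_is_near_zero(self):
        # fixed slice: all signal in the dead channel
        dead = np.ones((8, 8), dtype=bool)
        assert im.viability(np.zeros_like(dead), dead) == 0.0

    def test_both_empty_rejected(self):
        empty = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            im.viability(empty, empty)


def _nuclei_image(centers, size=128, sigma=2.5, amplitude=1.0):
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for r, c in centers:
        img += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return img


class TestCountNuclei:
    centers = [(r, c) for r in (20, 50, 80, 110) for c in (20, 60, 100)]

    def test_well_separated_gaussians(self):
        img = _nuclei_image(self.centers)
        tissue = np.ones(img.shape, dtype=bool)
        n, _ = im.count_nuclei(img, tissue)
        assert n == 12

    def test_blank_image_counts_zero(self):
        tissue = np.ones((64, 64), dtype=bool)
        assert im.count_nuclei(np.zeros((64, 64)), tissue)[0] == 0

    def test_closer_than_min_distance_merge(self):
        img = _nuclei_image([(32, 30), (32, 33)])
        tissue = np.ones(img.shape, dtype=bool)
        n, _ = im.count_nuclei(img, tissue, min_distance=5)
        assert n == 1

    def test_invariant_to_uniform_gain(self):
        img = _nuclei_image(self.centers)
        tissue = np.ones(img.shape, dtype=bool)
        assert im.count_nuclei(img, tissue)[0] == im.count_nuclei(img * 10.0, tissue)[0]


class TestMfiAndMarkers:
    def test_mfi_linearity_and_zero(self):
        tissue = np.ones((16, 16), dtype=bool)
        img = np.full((16, 16), 0.5)
        assert im.mfi_per_cell(np.zeros((16, 16)), tissue, 10) == 0.0
        one = im.mfi_per_cell(img, tissue, 10)
        assert im.mfi_per_cell(2 * img, tissue, 10) == pytest.approx(2 * one)
        with pytest.raises(ValueError):
            im.mfi_per_cell(img, tissue, 0)

    def test_marker_positive_fraction(self):
        centers = [(r, c) for r in (15, 40, 65, 90, 115) for c in (20, 45, 70, 95, 120)]
        marker = np.zeros((128, 128))
        for r, c in centers[:10]:  # 10 of 25 nuclei are marker-positive
            marker[r - 2 : r + 3, c - 2 : c + 3] = 1.0
        count, frac = im.marker_positive_count(marker, np.array(centers), threshold=0.5)
        assert count == 10
        assert frac == pytest.approx(0.40)

    def test_threshold_above_max_yields_zero(self):
        centers = np.array([[10, 10], [20, 20]])
        count, frac = im.marker_positive_count(np.ones((32, 32)), centers, threshold=2.0)
        assert count == 0 and frac == 0.0


class TestLongitudinalReport:
    def test_single_timepoint_single_row(self):
        series, _ = synth_timelapse(days=1, image_size=128, tissue_radius_mm=0.4, seed=0)
        report = im.longitudinal_report(series)
        assert len(report) == 1
        assert {"slice_area_mm2", "red_pct", "green_pct", "yellow_pct"} <= set(report.columns)

    def test_treated_series_green_is_cumulative(self):
        series, _ = synth_timelapse(days=8, image_size=192, tissue_radius_mm=0.7, seed=4)
        report = im.longitudinal_report(series)
        green = report["green_pct"].to_numpy()
        assert np.all(np.diff(green) >= -0.3)  # non-decreasing within pixel noise
        assert green[-1] > green[0]

    def test_control_series_green_flat_after_islet_labelling(self):
        series, _ = synth_timelapse(
            days=8, image_size=192, tissue_radius_mm=0.7, treated=False, seed=4
        )
        report = im.longitudinal_report(series)
        green = report["green_pct"].to_numpy()
        assert green[1] > green[0]  # islets label at day 1
        assert np.ptp(green[1:]) < 0.5
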