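import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage import draw, measure

from myelinquant import (
    CalibrationConfig,
    SceneSpec,
    detect_high_neuron,
    detect_oligodendrocytes,
    exclude_aggregates,
    exclude_dust,
    generate_coculture_field,
    score_cells,
    score_field,
)
from conftest import match_cells_to_truth


def disk_image(shape, centers, radius, values):
    g = np.zeros(shape)
    masks = []
    for c, v in zip(centers, values):
        rr, cc = draw.disk(c, radius, shape=shape)
        g[rr, cc] = v
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        masks.append(m)
    return g, masks


def brute_force_scan(grid, thresholds, min_area):
    """Exhaustive reference: threshold -> components -> size filter -> count."""
    counts = []
    for t in thresholds:
        lab = measure.label(grid > t, connectivity=2)
        areas = np.bincount(lab.ravel())[1:]
        counts.append(int(np.sum(areas >= min_area)))
    selected = float(thresholds[int(np.argmax(counts))])
    lab = measure.label(grid > selected, connectivity=2)
    areas = np.bincount(lab.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    return np.array(counts), selected, np.isin(lab, keep)


class TestDetectOligodendrocytes:
    def test_single_disk_counted_at_every_threshold(self, cal):
        radius = cal.expected_ol_diameter_px / 2.0
        g, _ = disk_image((256, 256), [(128, 128)], radius, [0.9])
        labels, scan = detect_oligodendrocytes(g, cal)
        assert np.all(scan.counts == 1)
        assert scan.selected == scan.thresholds[0]  # tie -> lowest
        assert labels.max() == 1

    def test_scan_reaches_down_to_dim_cells(self, cal):
        radius = cal.expected_ol_diameter_px / 2.0
        g, _ = disk_image(
            (512, 512), [(100, 100), (100, 400), (400, 250)], radius, [0.9, 0.9, 0.35]
        )
        labels, scan = detect_oligodendrocytes(g, cal)
        assert scan.counts.max() == 3
        assert scan.selected <= 0.35
        assert labels.max() == 3

    def test_size_floor_drops_small_objects(self, cal):
        # area = 0.1 x expected OL area, below the 20% floor
        radius = np.sqrt(0.1 * cal.expected_ol_area_px / np.pi)
        g, _ = disk_image((256, 256), [(128, 128)], radius, [0.9])
        labels, _ = detect_oligodendrocytes(g, cal)
        assert labels.max() == 0

    def test_matches_brute_force_oracle(self, small_scan_cal):
        rng = np.random.default_rng(11)
        min_area = small_scan_cal.size_floor_frac * small_scan_cal.expected_ol_area_px
        for _ in range(10):
            g = ndimage.gaussian_filter(rng.random((64, 64)), 3.0)
            thresholds = np.linspace(
                g.min() + 0.2 * (g.max() - g.min()),
                g.min() + 0.8 * (g.max() - g.min()),
                small_scan_cal.threshold_count,
            )
            exp_counts, exp_sel, exp_mask = brute_force_scan(g, thresholds, min_area)
            labels, scan = detect_oligodendrocytes(g, small_scan_cal)
            np.testing.assert_array_equal(scan.counts, exp_counts)
            assert scan.selected == pytest.approx(exp_sel, rel=1e-12)
            np.testing.assert_array_equal(labels > 0, exp_mask)


class TestDetectHighNeuron:
    def test_zero_neuron_empty_mask(self, cal):
        labels = np.ones((64, 64), dtype=np.int32)
        mask = detect_high_neuron(np.zeros((64, 64)), labels, cal)
        assert not mask.any()

    def test_saturated_neuron_covers_cells(self, cal):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[10:30, 10:30] = 1
        mask = detect_high_neuron(np.ones((64, 64)), labels, cal)
        np.testing.assert_array_equal(mask, labels > 0)

    def test_monotone_in_neuron_signal(self, cal):
        # adding neuron-positive pixels inside a cell never lowers its index;
        # adding them outside any cell changes nothing
        rng = np.random.default_rng(4)
        labels = np.zeros((128, 128), dtype=np.int32)
        labels[20:60, 20:60] = 1
        neuron = rng.random((128, 128)) * 0.5
        base = detect_high_neuron(neuron, labels, cal).sum()
        inside = neuron.copy()
        inside[30:40, 30:40] = 1.0
        assert detect_high_neuron(inside, labels, cal).sum() >= base
        outside = neuron.copy()
        outside[90:120, 90:120] = 1.0
        out_mask = detect_high_neuron(outside, labels, cal)
        assert out_mask.sum() == base
        assert not out_mask[90:120, 90:120].any()


class TestArtefactExclusion:
    def test_large_bright_disk_creates_zone(self, cal):
        g, _ = disk_image((300, 300), [(150, 150)], 50, [1.0])  # diameter 100 px
        labels = np.zeros_like(g, dtype=np.int32)
        zones, excluded = exclude_aggregates(g, labels, cal)
        assert zones.any()

    def test_thin_line_creates_no_zone(self, cal):
        g = np.zeros((300, 300))
        g[140:143, :] = 1.0  # 3 px wide, any length
        zones, _ = exclude_aggregates(g, np.zeros_like(g, dtype=np.int32), cal)
        assert not zones.any()

    def test_cell_swallowed_by_zone_excluded(self, cal):
        g, _ = disk_image((300, 300), [(150, 150)], 50, [1.0])
        labels = np.zeros_like(g, dtype=np.int32)
        labels[140:160, 140:160] = 1  # fully inside the aggregate
        labels[20:40, 20:60] = 2  # far away
        zones, excluded = exclude_aggregates(g, labels, cal)
        assert excluded == {1}

    def test_dust_disk_excluded_by_circularity(self, cal):
        labels = np.zeros((100, 100), dtype=np.int32)
        rr, cc = draw.disk((50, 50), 20)
        labels[rr, cc] = 1
        # oracle: 4 pi A / P^2 of the raster itself
        p = measure.regionprops(labels)[0]
        assert 4 * np.pi * p.area / p.perimeter**2 > 0.9
        assert exclude_dust(labels, cal.dust_circularity) == {1}

    def test_bar_retained(self, cal):
        labels = np.zeros((120, 120), dtype=np.int32)
        labels[10:14, 10:110] = 1  # 100 x 4 bar
        p = measure.regionprops(labels)[0]
        assert 4 * np.pi * p.area / p.perimeter**2 < 0.9
        assert exclude_dust(labels, cal.dust_circularity) == set()

    def test_star_shaped_ol_retained(self, cal):
        _, truth = generate_coculture_field(SceneSpec(seed=13, n_ols=1))
        labels = truth.ol_masks[0].astype(np.int32)
        p = measure.regionprops(labels)[0]
        assert 4 * np.pi * p.area / p.perimeter**2 < 0.9
        assert exclude_dust(labels, cal.dust_circularity) == set()


class TestScoreCells:
    def test_full_and_zero_overlap_are_exact(self, cal):
        for planted, expect in ((1.0, 1.0), (0.0, 0.0)):
            spec = SceneSpec(
                seed=21, planted_fractions=(planted,) * 4, impulse_fraction=0.0
            )
            img, truth = generate_coculture_field(spec)
            res = score_field(img, cal)
            matched = match_cells_to_truth(res, truth)
            assert len(matched) == 4
            for _, row in matched:
                assert row is not None
                assert row["myelination_index"] == expect

    def test_planted_fraction_recovered(self, cal):
        spec = SceneSpec(seed=22, planted_fractions=(0.4, 0.4, 0.4, 0.4))
        img, truth = generate_coculture_field(spec)
        res = score_field(img, cal)
        for planted, row in match_cells_to_truth(res, truth):
            assert row["myelination_index"] == pytest.approx(planted, abs=0.05)

    def test_bit_identical_on_repeat(self, cal):
        img, _ = generate_coculture_field(SceneSpec(seed=23))
        a = score_cells(img, cal)
        b = score_cells(img, cal)
        pd.testing.assert_frame_equal(a, b)

    def test_noisy_field_gated_out(self, cal):
        img, _ = generate_coculture_field(SceneSpec(seed=24, impulse_fraction=0.2))
        cells = score_cells(img, cal)
        assert cells.empty
        assert cells.attrs["excluded_reason"] == "noise"
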