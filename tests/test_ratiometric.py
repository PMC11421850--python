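"""Nuclei segmentation, 4-px cell rings, per-cell ratios and tracking."""

import numpy as np
import pytest
from skimage.draw import disk

from hypometrics import ratiometric, synthio
from hypometrics.types import InvalidInputError


class TestSegmentNuclei:
    def test_generator_truth_count(self, cell_images_3):
        imgset, truth = cell_images_3
        labels = ratiometric.segment_nuclei(imgset.channels[0]["RFP"])
        assert labels.max() == 3

    def test_blank_image_zero_labels(self):
        labels = ratiometric.segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_min_area_filter(self):
        img = np.zeros((80, 80))
        img[disk((20, 20), 8)] = 100.0
        img[disk((60, 60), 2)] = 100.0  # ~13 px, below min_area=20
        labels = ratiometric.segment_nuclei(img, min_area=20)
        assert labels.max() == 1


class TestExpandCells:
    def test_dilated_disk_area_matches_pixel_oracle(self):
        r = 6
        img = np.zeros((64, 64), dtype=np.int32)
        img[disk((32, 32), r + 0.5)] = 1
        cells = ratiometric.expand_cells(img)
        area = int((cells == 1).sum())
        expected = np.pi * (r + 4) ** 2
        # agreement within a one-pixel-wide boundary band
        assert abs(area - expected) < 2 * np.pi * (r + 4) + 10

    def test_empty_input_empty_output(self):
        out = ratiometric.expand_cells(np.zeros((32, 32), dtype=np.int32))
        assert out.max() == 0

    def test_close_nuclei_stay_disjoint(self):
        img = np.zeros((64, 64), dtype=np.int32)
        img[disk((32, 28), 2.5)] = 1
        img[disk((32, 34), 2.5)] = 2  # centers 6 px apart
        nucleus_union = (img > 0).sum()
        cells = ratiometric.expand_cells(img)
        assert set(np.unique(cells)) == {0, 1, 2}
        # nuclei keep their own label
        assert np.all(cells[img > 0] == img[img > 0])
        assert (cells > 0).sum() > nucleus_union

    def test_nucleus_subset_of_cell_and_masks_disjoint(self, cell_images_3):
        imgset, _ = cell_images_3
        nuclei = ratiometric.segment_nuclei(imgset.channels[0]["RFP"])
        cells = ratiometric.expand_cells(nuclei)
        assert np.all(cells[nuclei > 0] == nuclei[nuclei > 0])
        # disjointness is inherent to a single label array; check bounds
        assert cells.shape == nuclei.shape


class TestMeasureCells:
    def test_uniform_channels(self):
        cells = np.zeros((32, 32), dtype=np.int32)
        cells[disk((16, 16), 6)] = 1
        yfp = np.full((32, 32), 200.0)
        cfp = np.full((32, 32), 100.0)
        meas = ratiometric.measure_cells(cells, yfp, cfp)
        assert meas[0].ratio == pytest.approx(2.0)

    def test_identical_channels_ratio_one(self):
        cells = np.zeros((32, 32), dtype=np.int32)
        cells[disk((16, 16), 6)] = 1
        img = np.random.default_rng(0).uniform(50, 200, (32, 32))
        meas = ratiometric.measure_cells(cells, img, img)
        assert meas[0].ratio == pytest.approx(1.0)

    def test_generator_truth_exact(self, cell_images_3):
        imgset, truth = cell_images_3
        ch = imgset.channels[0]
        nuclei = ratiometric.segment_nuclei(ch["RFP"])
        cells = ratiometric.expand_cells(nuclei)
        meas = ratiometric.measure_cells(cells, ch["YFP"], ch["CFP"])
        got = sorted(m.ratio for m in meas)
        assert np.allclose(got, sorted(truth.params["true_ratios"]), rtol=1e-6)

    def test_zero_cfp_flagged(self):
        cells = np.zeros((16, 16), dtype=np.int32)
        cells[4:8, 4:8] = 1
        meas = ratiometric.measure_cells(cells, np.full((16, 16), 5.0), np.zeros((16, 16)))
        assert meas[0].flags == ["undefined"] and np.isnan(meas[0].ratio)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            ratiometric.measure_cells(np.zeros((8, 8), np.int32), np.zeros((9, 8)), np.zeros((8, 8)))

    def test_common_scale_invariance(self, cell_images_3):
        imgset, _ = cell_images_3
        ch = imgset.channels[0]
        nuclei = ratiometric.segment_nuclei(ch["RFP"])
        cells = ratiometric.expand_cells(nuclei)
        a = ratiometric.measure_cells(cells, ch["YFP"], ch["CFP"])
        b = ratiometric.measure_cells(cells, 3.7 * ch["YFP"], 3.7 * ch["CFP"])
        assert np.allclose([m.ratio for m in a], [m.ratio for m in b])


class TestImageSummary:
    def test_mean_and_count(self):
        meas = [
            ratiometric.CellMeasurement(i, 0, 1, r) for i, r in enumerate([1.0, 2.0, 3.0])
        ]
        assert ratiometric.image_summary(meas) == (pytest.approx(2.0), 3)

    def test_empty_undefined(self):
        mean, n = ratiometric.image_summary([])
        assert np.isnan(mean) and n == 0

    def test_single_cell(self):
        meas = [ratiometric.CellMeasurement(1, 0, 1, 1.7)]
        assert ratiometric.image_summary(meas)[0] == pytest.approx(1.7)


class TestRatioImage:
    def test_equal_channels_all_ones(self):
        img = np.full((16, 16), 80.0)
        assert np.allclose(ratiometric.ratio_image(img, img), 1.0)

    def test_zero_cfp_bounded(self):
        yfp = np.full((8, 8), 10.0)
        out = ratiometric.ratio_image(yfp, np.zeros((8, 8)), epsilon=2.0)
        assert np.all(np.isfinite(out)) and np.all(out == 5.0)

    def test_double_ratio(self):
        cfp = np.random.default_rng(1).uniform(10, 100, (8, 8))
        out = ratiometric.ratio_image(2 * cfp, cfp, epsilon=1e-6)
        assert np.allclose(out, 2.0)


class TestTracking:
    def test_static_cells_full_tracks(self):
        imgset, truth = synthio.gen_cell_images(
            n_cells=4, image_size=200, n_timepoints=5, noise_sd=0.0, seed=13
        )
        table, tracks = ratiometric.track_timecourse(imgset)
        assert len(table) == 5
        full = [t for t in tracks if len(t) == 5]
        assert len(full) == 4

    def test_grid_violation_rejected(self):
        imgset, _ = synthio.gen_cell_images(n_cells=2, image_size=160, seed=1)
        imgset.timepoints = np.array([7.0])
        with pytest.raises(InvalidInputError):
            ratiometric.track_timecourse(imgset)

    def test_empty_series_summary_rows_still_emitted(self):
        imgset, _ = synthio.gen_cell_images(n_cells=2, image_size=160, seed=1)
        blank = {k: np.zeros_like(v) for k, v in imgset.channels[0].items()}
        imgset.channels = [blank]
        table, tracks = ratiometric.track_timecourse(imgset)
        assert len(table) == 1 and table["qc_flag"].iloc[0] == "undefined"
        assert tracks == []
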