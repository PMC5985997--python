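"""Intensity quantification tests: background, per-cell means, summaries,
and the Welch comparison, on programmable synthetic fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fcsquant.images import CellImage, ImageSimConfig, simulate_cell_image
from fcsquant.quantify import (
    IntensityRecord,
    compare_promoters,
    measure_cells,
    subtract_background,
    summarize_promoters,
)


def _image(n_cells, intensities, labels, **overrides):
    kwargs = dict(
        image_shape=(512, 512),
        background_level=100.0,
        noise_sd=4.0,
        n_cells=n_cells,
        cell_mean_intensities=intensities,
        promoter_labels=labels,
        seed=3,
    )
    kwargs.update(overrides)
    return simulate_cell_image(ImageSimConfig(**kwargs))


def _records(label, values, start_id=1, saturated=False):
    return [
        IntensityRecord(start_id + i, label, float(v), 1000, saturated)
        for i, v in enumerate(values)
    ]


class TestBackground:
    def test_uniform_image_minus_its_background_is_zero(self):
        img = np.full((64, 64), 100.0)
        assert np.all(subtract_background(img, 100.0) == 0.0)

    def test_zero_background_is_identity(self):
        img = np.full((64, 64), 321.0)
        np.testing.assert_array_equal(subtract_background(img, 0.0), img)

    def test_plateau_above_background(self):
        img = _image(1, [400.0], ["A"], noise_sd=0.0)
        corrected = subtract_background(img, 100.0)
        assert corrected[img.cell_mask(1)].mean() == pytest.approx(400.0)

    def test_background_estimated_from_unmasked_region(self):
        img = _image(1, [400.0], ["A"], noise_sd=0.0)
        corrected = subtract_background(img)  # mean outside masks = 100
        assert corrected[img.cell_mask(1)].mean() == pytest.approx(
            400.0, abs=0.5)

    def test_excessive_background_warns(self):
        img = np.full((64, 64), 50.0)
        with pytest.warns(UserWarning, match="exceeds"):
            out = subtract_background(img, 80.0)
        assert np.all(out == 0.0)

    def test_background_invariance_of_corrected_means(self):
        """Adding a constant to image and background leaves records fixed."""
        img = _image(2, [400.0, 100.0], ["A", "B"], noise_sd=0.0)
        r0 = measure_cells(img, 100.0)
        shifted = CellImage(
            pixels=img.pixels + 500, masks=img.masks,
            ground_truth=img.ground_truth, metadata=img.metadata,
        )
        r1 = measure_cells(shifted, 600.0)
        for a, b in zip(r0, r1):
            assert a.mean_intensity == pytest.approx(b.mean_intensity,
                                                     abs=1e-9)


class TestMeasureCells:
    def test_known_mean_recovered_within_one_percent(self):
        img = _image(1, [400.0], ["A"], cell_radius_range=(30.0, 35.0))
        rec = measure_cells(img, 100.0)[0]
        assert rec.n_pixels >= 1000
        assert rec.mean_intensity == pytest.approx(400.0, rel=0.01)

    def test_saturated_mask_flagged(self):
        pixels = np.full((64, 64), 65535, dtype=np.uint16)
        masks = np.zeros((64, 64), dtype=np.uint16)
        masks[10:30, 10:30] = 1
        img = CellImage(pixels=pixels, masks=masks,
                        ground_truth=pd.DataFrame())
        rec = measure_cells(img, 0.0)[0]
        assert rec.saturated

    def test_foci_included_in_whole_cell_mean(self):
        img = _image(1, [400.0], ["A"], noise_sd=0.0,
                     foci_per_cell=4, foci_amplitude=2000.0)
        rec = measure_cells(img, 100.0)[0]
        truth = img.ground_truth.iloc[0].true_mean_above_background
        assert truth > 400.0
        assert rec.mean_intensity == pytest.approx(truth, rel=5e-3)


class TestSummaries:
    def test_programmed_ratio_and_reference_scaling(self):
        recs = (_records("A", 40 + np.zeros(10))
                + _records("B", 10 + np.zeros(10), start_id=11))
        summaries = {s.promoter_label: s
                     for s in summarize_promoters(recs, "B", 10.0)}
        assert summaries["B"].normalized_mean == pytest.approx(10.0)
        assert summaries["A"].normalized_mean == pytest.approx(40.0)
        assert all(s.reportable for s in summaries.values())

    def test_self_reference_reads_exactly_ten(self):
        recs = _records("A", np.linspace(20, 30, 12))
        (s,) = summarize_promoters(recs, "A", 10.0)
        assert s.normalized_mean == pytest.approx(10.0, rel=1e-12)

    def test_normalization_is_scale_invariant(self):
        """Summarizing pre-scaled records reproduces the same normalized
        means: renormalizing with the same reference is the identity."""
        rng = np.random.default_rng(0)
        vals_a, vals_b = rng.uniform(30, 50, 10), rng.uniform(8, 12, 10)
        recs = _records("A", vals_a) + _records("B", vals_b, start_id=11)
        first = {s.promoter_label: s.normalized_mean
                 for s in summarize_promoters(recs, "B", 10.0)}
        scale = 10.0 / np.mean(vals_b)
        rescaled = (_records("A", vals_a * scale)
                    + _records("B", vals_b * scale, start_id=11))
        second = {s.promoter_label: s.normalized_mean
                  for s in summarize_promoters(rescaled, "B", 10.0)}
        for k in first:
            assert second[k] == pytest.approx(first[k], rel=1e-12)

    def test_small_groups_flagged_non_reportable(self):
        recs = (_records("A", np.full(9, 40.0))
                + _records("REF", np.full(10, 10.0), start_id=10))
        summaries = {s.promoter_label: s
                     for s in summarize_promoters(recs, "REF", 10.0)}
        assert not summaries["A"].reportable
        assert summaries["REF"].reportable

    def test_saturated_constructs_out_of_range(self):
        recs = (_records("HOT", np.full(10, 900.0), saturated=True)
                + _records("REF", np.full(10, 10.0), start_id=11))
        summaries = {s.promoter_label: s
                     for s in summarize_promoters(recs, "REF", 10.0)}
        assert summaries["HOT"].out_of_range
        assert np.isnan(summaries["HOT"].normalized_mean)

    def test_missing_or_thin_reference_rejected(self):
        recs = _records("A", np.full(10, 40.0))
        with pytest.raises(ValueError, match="absent"):
            summarize_promoters(recs, "NOPE")
        with pytest.raises(ValueError, match="needs >="):
            summarize_promoters(_records("A", np.full(5, 40.0)), "A")


class TestComparison:
    def test_fourfold_difference_detected(self, rng):
        """N(40, 4^2) vs N(10, 2^2), n = 10: the ratio is ~4 and the
        Welch test is significant in nearly every draw."""
        hits = 0
        ratios = []
        for _ in range(200):
            a = rng.normal(40, 4, 10)
            b = rng.normal(10, 2, 10)
            cmp_ = compare_promoters(a, b)
            ratios.append(cmp_.ratio)
            hits += cmp_.p_value < 0.01
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.05)
        assert hits / 200 >= 0.95

    def test_null_calibration_type_i_error(self, rng):
        """Identical groups: p < 0.05 in about 5% of 500 draws."""
        hits = sum(
            compare_promoters(rng.normal(10, 2, 10),
                              rng.normal(10, 2, 10)).p_value < 0.05
            for _ in range(500)
        )
        assert 0.02 <= hits / 500 <= 0.09

    def test_degenerate_zero_variance(self):
        cmp_ = compare_promoters([5.0, 5.0], [1.0, 1.0])
        assert cmp_.ratio == pytest.approx(5.0)
        assert np.isnan(cmp_.p_value)

    def test_tiny_groups_do_not_crash(self, rng):
        cmp_ = compare_promoters(rng.normal(40, 4, 2), rng.normal(10, 2, 2))
        assert np.isfinite(cmp_.ratio)


class TestEndToEndRatio:
    def test_image_pipeline_recovers_programmed_ratio(self):
        """Two constructs programmed 4:1 over 10 cells each on one frame
        set: normalized means recover the ratio within 5%."""
        records = []
        for seed in range(4):
            img = _image(
                6, [400.0, 400.0, 400.0, 100.0, 100.0, 100.0],
                ["A", "A", "A", "B", "B", "B"],
                seed=20 + seed, noise_sd=4.0,
            )
            recs = measure_cells(img, 100.0)
            for r in recs:
                r.cell_id += seed * 100
            records.extend(recs)
        summaries = {s.promoter_label: s
                     for s in summarize_promoters(records, "B", 10.0)}
        assert summaries["A"].n_cells >= 10 and summaries["B"].n_cells >= 10
        assert summaries["B"].normalized_mean == pytest.approx(10.0)
        assert summaries["A"].normalized_mean == pytest.approx(40.0, rel=0.05)
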