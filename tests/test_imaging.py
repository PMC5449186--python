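"""Segmentation, N/T measurement, time-course normalization, t-tests."""

import math

import numpy as np
import pandas as pd
import pytest

from crypticnes.imaging import (
    CellImage,
    NormalizationError,
    measure_nt,
    measurements_frame,
    normalize_timecourse,
    segment_cells,
)
from crypticnes.stats import two_sample_ttest
from crypticnes.synthetic import ImageSimConfig, gen_cell_images


def simulate_image(**kwargs) -> tuple[CellImage, pd.DataFrame]:
    cfg = ImageSimConfig(**kwargs)
    signal, nuclei, truth = gen_cell_images(cfg)
    return CellImage(signal, nuclei), truth


class TestSegmentCells:
    def test_five_isolated_cells_found(self):
        image, truth = simulate_image(n_cells=5, seed=1)
        masks = segment_cells(image)
        assert len(masks) == 5
        for m in masks:
            assert m.nucleus.sum() > 0
            assert np.all(m.cell[m.nucleus])  # nucleus inside cell

    def test_blank_image_warns_and_returns_empty(self):
        blank = CellImage(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.warns(UserWarning, match="no cells"):
            assert segment_cells(blank) == []

    def test_border_cells_discarded(self):
        image, truth = simulate_image(n_cells=4, n_border=2, seed=3)
        assert len(truth) == 6 and truth["border"].sum() == 2
        assert len(segment_cells(image)) == 4


class TestMeasureNT:
    def test_uniform_intensity_ratio_equals_area_fraction(self):
        # noiseless flat cell: summed intensities reduce to pixel counts
        signal = np.zeros((64, 64))
        nuclei = np.zeros((64, 64))
        yy, xx = np.ogrid[:64, :64]
        cell = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        nuc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 11**2
        signal[cell] = 50.0
        nuclei[nuc] = 50.0
        image = CellImage(signal, nuclei)
        (m,) = measure_nt(image, segment_cells(image))
        assert m.ratio == pytest.approx(nuc.sum() / cell.sum(), abs=0.02)

    def test_zero_nuclear_intensity_gives_zero_ratio(self):
        signal = np.zeros((64, 64))
        nuclei = np.zeros((64, 64))
        yy, xx = np.ogrid[:64, :64]
        cell = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        nuc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2
        signal[cell & ~nuc] = 50.0  # nucleus dark in the signal channel
        nuclei[nuc] = 50.0
        image = CellImage(signal, nuclei)
        (m,) = measure_nt(image, segment_cells(image))
        assert m.ratio == pytest.approx(0.0, abs=1e-6)

    def test_ratio_recovery_within_005_at_snr_10(self):
        image, truth = simulate_image(n_cells=30, nuclear_fraction=0.5, seed=11)
        measurements = measure_nt(image, segment_cells(image))
        assert len(measurements) >= 28
        mean_ratio = np.mean([m.ratio for m in measurements])
        assert abs(mean_ratio - 0.5) <= 0.05

    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_ratio_recovery_across_fractions(self, f):
        image, truth = simulate_image(n_cells=30, nuclear_fraction=f, seed=int(f * 100))
        measurements = measure_nt(image, segment_cells(image))
        mean_ratio = np.mean([m.ratio for m in measurements])
        assert abs(mean_ratio - f) <= 0.05

    def test_invariant_to_global_additive_offset(self):
        image, _ = simulate_image(n_cells=10, seed=7)
        masks = segment_cells(image)
        base = [m.ratio for m in measure_nt(image, masks)]
        offset_img = CellImage(image.signal + 40.0, image.nuclei)
        shifted = [m.ratio for m in measure_nt(offset_img, masks)]
        assert np.allclose(base, shifted, atol=0.02)

    def test_ratios_bounded_zero_one(self):
        image, _ = simulate_image(n_cells=20, nuclear_fraction=0.9, seed=13)
        for m in measure_nt(image, segment_cells(image)):
            assert 0.0 <= m.ratio <= 1.0


class TestNormalizeTimecourse:
    def test_direct_division(self):
        frame = pd.DataFrame(
            {
                "group": ["g"] * 9,
                "time_min": [0, 0, 0, 30, 30, 30, 60, 60, 60],
                "ratio": [0.40, 0.40, 0.40, 0.20, 0.20, 0.20, 0.10, 0.10, 0.10],
            }
        )
        (tc,) = normalize_timecourse(frame)
        assert tc.normalized_mean == pytest.approx((1.0, 0.5, 0.25))

    def test_t0_mean_exactly_one_per_group(self):
        rng = np.random.default_rng(21)
        rows = []
        for group, base in [("CHX", 0.5), ("CHX+LMB", 0.4)]:
            for t in (0.0, 30.0, 60.0):
                for _ in range(30):
                    rows.append(
                        {"group": group, "time_min": t, "ratio": base * rng.uniform(0.8, 1.2)}
                    )
        for tc in normalize_timecourse(pd.DataFrame(rows)):
            assert tc.normalized_mean[0] == 1.0  # exact, not approximate

    def test_single_time_point(self):
        frame = pd.DataFrame({"group": ["g"] * 3, "time_min": [0] * 3, "ratio": [0.3, 0.4, 0.5]})
        (tc,) = normalize_timecourse(frame)
        assert tc.normalized_mean == (1.0,)

    def test_sem_scaled_by_same_factor(self):
        frame = pd.DataFrame(
            {"group": ["g"] * 6, "time_min": [0, 0, 0, 30, 30, 30], "ratio": [0.4, 0.5, 0.6, 0.2, 0.25, 0.3]}
        )
        (tc,) = normalize_timecourse(frame)
        t0_mean = np.mean([0.4, 0.5, 0.6])
        assert tc.normalized_sem[0] == pytest.approx(tc.sem[0] / t0_mean)

    def test_missing_t0_raises(self):
        frame = pd.DataFrame({"group": ["g"] * 2, "time_min": [30, 30], "ratio": [0.2, 0.3]})
        with pytest.raises(NormalizationError):
            normalize_timecourse(frame)


class TestTwoSampleTTest:
    def test_identical_samples_paired_gives_p_one(self):
        cmp = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert cmp.t == 0.0 and cmp.p == 1.0

    def test_complete_separation_unpaired(self):
        cmp = two_sample_ttest([1, 2, 3], [11, 12, 13])
        assert cmp.p < 0.001

    def test_matches_textbook_formula_to_1e10(self):
        """Pooled-variance t and two-tailed p, recomputed from the
        textbook formulas, must agree to 1e-10."""
        from scipy.stats import t as tdist

        a = [1.1, 2.3, 3.1, 4.0, 5.2, 6.1, 7.3, 8.0, 9.1, 10.2]
        b = [2.0, 3.1, 4.5, 5.0, 6.2, 7.1, 8.3, 9.0, 10.1, 11.9]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_expected = 2 * tdist.sf(abs(t_expected), na + nb - 2)
        cmp = two_sample_ttest(a, b)
        assert abs(cmp.t - t_expected) < 1e-10
        assert abs(cmp.p - p_expected) < 1e-10
        assert cmp.df == na + nb - 2

    def test_paired_matches_difference_formula(self):
        from scipy.stats import t as tdist

        a = np.array([0.9, 1.1, 1.3, 1.0, 1.2, 0.8])
        b = np.array([1.0, 1.3, 1.6, 1.2, 1.5, 1.1])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_expected = 2 * tdist.sf(abs(t_expected), len(d) - 1)
        cmp = two_sample_ttest(a, b, paired=True)
        assert abs(cmp.t - t_expected) < 1e-10
        assert abs(cmp.p - p_expected) < 1e-10

    def test_input_validation(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            two_sample_ttest([1, 2, 3], [1, 2], paired=True)


def test_measurements_frame_columns():
    image, _ = simulate_image(n_cells=3, seed=2)
    frame = measurements_frame(measure_nt(image, segment_cells(image)))
    assert list(frame.columns) == ["cell_id", "group", "time_min", "N", "T", "ratio"]
    assert len(frame) == 3
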