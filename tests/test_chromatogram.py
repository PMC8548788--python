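"""Signal processing: I/O round trips, baseline, detection, integration."""

import numpy as np
import pytest

from herbqc.chromatogram import (
    Chromatogram,
    Peak,
    baseline_correct,
    build_peak_table,
    detect_peaks,
    integrate_peak,
    match_peaks,
    read_chromatogram,
    write_chromatogram,
)
from herbqc.synthetic_data import default_design, simulate_study


def gaussian_trace(centers, heights, sd=0.08, t_max=27.0, step=0.004, slope=0.0, offset=0.0):
    t = np.arange(0.0, t_max + step / 2, step)
    y = offset + slope * t
    for c, h in zip(centers, heights):
        y = y + h * np.exp(-0.5 * ((t - c) / sd) ** 2)
    return Chromatogram(time=t, intensity=y, sample_id="toy")


class TestIO:
    def test_round_trip(self, tmp_path):
        c = gaussian_trace([10.0], [50.0])
        path = tmp_path / "toy.csv"
        write_chromatogram(c, path)
        back = read_chromatogram(path)
        assert np.allclose(back.time, c.time, atol=1e-9)
        assert np.allclose(back.intensity, c.intensity, atol=1e-9)

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_min,intensity_mAU\n0.0,1\n0.2,1\n0.1,1\n")
        with pytest.raises(ValueError, match="increasing"):
            read_chromatogram(path)

    def test_missing_header_names_expected_columns(self, tmp_path):
        path = tmp_path / "headerless.csv"
        path.write_text("a,b\n0.0,1\n0.1,1\n")
        with pytest.raises(ValueError, match="time_min"):
            read_chromatogram(path)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            Chromatogram(time=[0.0], intensity=[1.0])
        with pytest.raises(ValueError, match="irregular"):
            Chromatogram(time=[0.0, 0.1, 0.3], intensity=[1.0, 1.0, 1.0])


class TestBaseline:
    def test_flat_trace_goes_to_zero(self):
        c = gaussian_trace([], [], offset=5.0)
        out = baseline_correct(c)
        assert np.allclose(out.intensity, 0.0, atol=1e-9)

    def test_linear_ramp_goes_to_zero(self):
        c = gaussian_trace([], [], slope=0.5, offset=2.0)
        out = baseline_correct(c)
        assert np.abs(out.intensity).max() < 1e-9

    def test_gaussian_on_ramp_recovers_area(self):
        h, sd = 80.0, 0.08
        c = gaussian_trace([12.0], [h], sd=sd, slope=0.3, offset=1.0)
        out = baseline_correct(c)
        mask = np.abs(out.time - 12.0) <= 5 * sd
        area = np.trapezoid(out.intensity[mask], out.time[mask])
        assert area == pytest.approx(h * sd * np.sqrt(2 * np.pi), rel=0.01)


class TestDetection:
    def test_zero_trace_empty(self):
        c = gaussian_trace([], [])
        assert detect_peaks(c) == []

    def test_single_gaussian_found_at_center(self):
        c = gaussian_trace([10.0], [50.0])
        peaks = detect_peaks(c)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 10.0) <= 0.004  # within one grid step

    def test_two_gaussians_one_minute_apart(self):
        c = gaussian_trace([10.0, 11.0], [50.0, 30.0])
        assert len(detect_peaks(c)) == 2


class TestIntegration:
    def test_unit_triangle(self):
        t = np.linspace(9.0, 11.0, 2001)
        y = np.clip(1.0 - np.abs(t - 10.0) / 0.5, 0.0, None)
        c = Chromatogram(time=t, intensity=y)
        p = Peak(apex_time=10.0, left_bound=9.5, right_bound=10.5, height=1.0)
        assert integrate_peak(c, p) == pytest.approx(0.5, rel=1e-4)

    def test_gaussian_closed_form(self):
        h, sd = 100.0, 0.08
        c = gaussian_trace([10.0], [h], sd=sd)
        p = Peak(apex_time=10.0, left_bound=10.0 - 4 * sd, right_bound=10.0 + 4 * sd, height=h)
        assert integrate_peak(c, p) == pytest.approx(h * sd * np.sqrt(2 * np.pi), rel=0.01)

    def test_zero_signal(self):
        c = gaussian_trace([], [])
        p = Peak(apex_time=10.0, left_bound=9.5, right_bound=10.5, height=1.0)
        assert integrate_peak(c, p) == 0.0

    def test_bounds_outside_grid(self):
        c = gaussian_trace([], [])
        p = Peak(apex_time=10.0, left_bound=-1.0, right_bound=10.5, height=1.0)
        with pytest.raises(ValueError, match="outside"):
            integrate_peak(c, p)

    def test_matches_fine_grid_oracle_for_generator_peaks(self):
        """Detected-bounds integration within 0.5% of a 10x-finer trapezoid."""
        heights = [400.0, 90.0, 1500.0]
        centers = [5.0, 12.0, 20.0]
        c = gaussian_trace(centers, heights)
        peaks = detect_peaks(c)
        assert len(peaks) == 3
        fine_t = np.arange(0.0, 27.0, 0.0004)
        for p, ctr, h in zip(peaks, centers, heights):
            fine = h * np.exp(-0.5 * ((fine_t - ctr) / 0.08) ** 2)
            oracle = np.trapezoid(fine, fine_t)
            assert p.area == pytest.approx(oracle, rel=0.005)


class TestMatching:
    def make(self, rt):
        return Peak(apex_time=rt, left_bound=rt - 0.3, right_bound=rt + 0.3, height=10.0)

    def test_within_tolerance_matched(self):
        a = match_peaks([self.make(10.05)], [10.0], tolerance=0.2)
        assert 0 in a.matched and a.unmatched_references == []

    def test_outside_tolerance_unmatched(self):
        a = match_peaks([self.make(10.3)], [10.0], tolerance=0.2)
        assert a.matched == {} and a.unmatched_references == [0]

    def test_equidistant_tie_takes_earlier_peak(self):
        a = match_peaks([self.make(9.9), self.make(10.1)], [10.0], tolerance=0.2)
        assert a.matched[0].apex_time == 9.9

    def test_conflict_resolved_by_distance_then_reference_order(self):
        # one peak exactly equidistant from two references (binary-exact
        # values so no float noise breaks the tie): the earlier reference wins
        a = match_peaks([self.make(10.5)], [10.0, 11.0], tolerance=0.6)
        assert list(a.matched) == [0]
        assert a.unmatched_references == [1]


class TestPeakTable:
    def test_fifteen_batches_ten_common_peaks(self, table6):
        """The default study yields the full 10-common-peak fingerprint."""
        design = default_design(1).noiseless().proportional_response()
        contents = table6[[c for c in table6.columns if c.endswith("_esm")]].copy()
        contents.columns = [c[:-4] for c in contents.columns]
        chroms = simulate_study(design, contents, seed=2)
        corrected = [baseline_correct(c) for c in chroms]
        samples = [(c, detect_peaks(c, min_height=0.5)) for c in corrected]
        table = build_peak_table(samples, design.all_retention_times(), design.peak_labels())
        assert table.areas.shape == (15, 10)
        assert (table.compounds != "").sum() == 6

    def test_duplicated_sample_gives_identical_rows(self):
        c1 = gaussian_trace([5.0, 10.0], [50.0, 80.0])
        c1.sample_id = "A"
        c2 = gaussian_trace([5.0, 10.0], [50.0, 80.0])
        c2.sample_id = "B"
        samples = [(c, detect_peaks(c)) for c in (c1, c2)]
        table = build_peak_table(samples, [5.0, 10.0])
        assert np.allclose(table.areas.loc["A"], table.areas.loc["B"])

    def test_missing_peak_excluded_from_common_set(self, caplog):
        c1 = gaussian_trace([5.0, 10.0], [50.0, 80.0])
        c1.sample_id = "A"
        c2 = gaussian_trace([5.0], [50.0])  # second peak absent
        c2.sample_id = "B"
        samples = [(c, detect_peaks(c)) for c in (c1, c2)]
        table = build_peak_table(samples, [5.0, 10.0])
        assert table.areas.shape[1] == 1
        assert table.retention_times.iloc[0] == pytest.approx(5.0)

    def test_no_common_peaks_raises(self):
        c1 = gaussian_trace([5.0], [50.0])
        c1.sample_id = "A"
        c2 = gaussian_trace([10.0], [50.0])
        c2.sample_id = "B"
        samples = [(c, detect_peaks(c)) for c in (c1, c2)]
        with pytest.raises(ValueError, match="no common peaks"):
            build_peak_table(samples, [15.0, 20.0])
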