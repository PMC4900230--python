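"""File I/O, cropping and baseline handling of Raman spectra."""

import numpy as np
import pytest

from carbscreen import (Band, BandShape, RamanSpectrum, SampleRecord,
                        crop_window, evaluate_band, read_spectrum,
                        subtract_linear_baseline, write_spectrum, write_table)
from carbscreen.spectra import read_table


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadSpectrum:
    def test_identity_read(self, tmp_path):
        w = np.linspace(800, 2000, 1001)
        y = np.sin(w / 100) + 2
        p = _write(tmp_path, "s.txt", [f"{a} {b}" for a, b in zip(w, y)])
        s = read_spectrum(p)
        assert len(s) == 1001
        np.testing.assert_allclose(s.wavenumber, w)
        np.testing.assert_allclose(s.intensity, y)

    def test_descending_file_sorted_ascending(self, tmp_path):
        w = np.linspace(800, 2000, 200)[::-1]
        p = _write(tmp_path, "s.txt", [f"{a},{a * 2}" for a in w])
        s = read_spectrum(p)
        assert np.all(np.diff(s.wavenumber) > 0)
        np.testing.assert_allclose(s.intensity, s.wavenumber * 2)

    def test_header_and_comments_skipped(self, tmp_path):
        rows = ["wavenumber\tintensity", "# acquired 2016-01-01"]
        rows += [f"{800 + i}\t{1.0 + i}" for i in range(60)]
        s = read_spectrum(_write(tmp_path, "s.tsv", rows))
        assert len(s) == 60

    def test_duplicate_wavenumbers_averaged(self, tmp_path):
        rows = [f"{800 + i} 1.0" for i in range(60)] + ["800 3.0"]
        s = read_spectrum(_write(tmp_path, "s.txt", rows))
        assert len(s) == 60
        assert s.intensity[0] == pytest.approx(2.0)  # (1 + 3) / 2

    def test_too_few_points_rejected(self, tmp_path):
        p = _write(tmp_path, "s.txt", [f"{i} 1.0" for i in range(10)])
        with pytest.raises(ValueError, match="50"):
            read_spectrum(p)

    def test_write_read_roundtrip_to_6_digits(self, tmp_path):
        w = np.linspace(1000, 1800, 801)
        y = np.exp(-((w - 1350.0) / 90) ** 2) * 123.456
        s = RamanSpectrum(w, y, sample_id="rt")
        back = read_spectrum(write_spectrum(s, tmp_path / "rt.txt"))
        np.testing.assert_allclose(back.wavenumber, w, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, y, rtol=1e-5, atol=1e-6 * y.max())


class TestSpectrumInvariants:
    def test_non_increasing_wavenumbers_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            RamanSpectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            RamanSpectrum(np.array([1.0, 2.0]), np.array([np.nan, 0.0]))


class TestCropWindow:
    def test_point_count(self, grid):
        s = RamanSpectrum(np.arange(800.0, 2001.0), np.ones(1201))
        assert len(crop_window(s, 1000, 1800)) == 801

    def test_full_range_identity(self, grid):
        s = RamanSpectrum(grid, np.ones_like(grid))
        c = crop_window(s, grid[0], grid[-1])
        np.testing.assert_array_equal(c.wavenumber, s.wavenumber)

    def test_empty_window_errors(self, grid):
        s = RamanSpectrum(grid, np.ones_like(grid))
        with pytest.raises(ValueError, match="no data"):
            crop_window(s, 3000, 3500)


class TestBaseline:
    def test_pure_line_cancels_exactly(self, grid):
        s = RamanSpectrum(grid, 3.0 + 0.01 * grid)
        out = subtract_linear_baseline(s)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_lorentzian_on_line_recovered(self, grid):
        band = Band("D1", BandShape.LORENTZIAN, 1350.0, 1.0, 60.0)
        pure = evaluate_band(band, grid)
        s = RamanSpectrum(grid, pure + 5.0 - 0.002 * grid)
        out = subtract_linear_baseline(s)
        # anchor windows sit on the band's tails: height distortion <= 1%
        assert abs(out.intensity.max() - 1.0) <= 0.01

    def test_flat_zero_unchanged(self, grid):
        out = subtract_linear_baseline(RamanSpectrum(grid, np.zeros_like(grid)))
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_idempotent_on_noiseless_input(self, grid):
        s = RamanSpectrum(grid, 2.0 + 0.003 * grid + np.exp(-((grid - 1400) / 200) ** 2))
        once = subtract_linear_baseline(s)
        twice = subtract_linear_baseline(once)
        scale = np.abs(once.intensity).max()
        assert np.abs(twice.intensity - once.intensity).max() < 1e-9 * max(scale, 1.0)

    def test_empty_anchor_errors(self, grid):
        s = RamanSpectrum(grid, np.ones_like(grid))
        with pytest.raises(ValueError, match="anchor"):
            subtract_linear_baseline(s, anchors=((200, 300), (1700, 1800)))


class TestSampleRecord:
    def test_archean_flag_auto_derived(self):
        assert SampleRecord("a", 2.65).is_archean
        assert not SampleRecord("b", 1.9).is_archean

    def test_percentage_bounds(self):
        with pytest.raises(ValueError):
            SampleRecord("a", 1.0, h_wt=120.0)


class TestWriteTable:
    def test_fixture_row_count(self, tmp_path):
        from carbscreen import load_fixture
        rows = [{"sample_id": fs.record.sample_id, "age_Ga": fs.record.age_Ga,
                 "r1": fs.params.r1} for fs in load_fixture()]
        path = write_table(rows, tmp_path / "t.csv")
        text = path.read_text().strip().splitlines()
        assert len(text) == 18  # header + 17 samples

    def test_empty_list_errors(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_table([], tmp_path / "t.csv")

    def test_single_record_roundtrip(self, tmp_path):
        row = {"sample_id": "x", "age_Ga": 3.0, "r1": 1.5, "fwhm_d1": 70.0}
        df = read_table(write_table([row], tmp_path / "t.csv"))
        assert len(df) == 1
        for k, v in row.items():
            assert df.iloc[0][k] == v
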