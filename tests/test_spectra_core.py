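"""Core types, absorbance conversion and CSV round-trips."""

import numpy as np
import pytest

from beernir.spectra_core import (
    CLASSES,
    ScanTriplet,
    SpectraSet,
    WavelengthGrid,
    absorbance_from_intensity,
    average_scans,
    read_spectra_csv,
    write_spectra_csv,
)


class TestWavelengthGrid:
    def test_default_grid_is_900_to_1700_with_228_points(self):
        g = WavelengthGrid.default()
        assert g.n_points == 228
        assert g.wavelengths[0] == 900.0
        assert g.wavelengths[-1] == 1700.0
        assert np.all(np.diff(g.wavelengths) > 0)

    def test_rejects_non_increasing_axis(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WavelengthGrid(np.array([900.0, 900.0, 901.0]))

    def test_rejects_scalar_or_short_axis(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([900.0]))

    def test_band_mask_is_inclusive(self):
        g = WavelengthGrid(np.array([900.0, 1000.0, 1100.0, 1200.0]))
        assert g.band_mask(1000.0, 1100.0).tolist() == [False, True, True, False]


class TestAbsorbance:
    def test_beer_lambert_conversion(self):
        I0 = np.array([1.0, 1.0, 2.0])
        I = np.array([0.1, 1.0, 0.2])
        A = absorbance_from_intensity(I, I0)
        assert A == pytest.approx([1.0, 0.0, 1.0])

    def test_zero_intensity_error_names_the_index(self):
        with pytest.raises(ValueError, match="sample intensity at index 1"):
            absorbance_from_intensity(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="background intensity at index 0"):
            absorbance_from_intensity(np.array([1.0, 1.0]), np.array([-1.0, 1.0]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            absorbance_from_intensity(np.ones(3), np.ones(4))

    def test_average_scans_is_per_wavelength_mean(self):
        scans = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        t = ScanTriplet(scans=scans, background=np.ones(2))
        assert average_scans(t) == pytest.approx([3.0, 4.0])

    def test_scan_triplet_validation(self):
        with pytest.raises(ValueError, match=r"\(3, P\)"):
            ScanTriplet(scans=np.ones((2, 5)), background=np.ones(5))
        with pytest.raises(ValueError, match="> 0"):
            ScanTriplet(scans=np.zeros((3, 5)), background=np.ones(5))


class TestSpectraSet:
    def _grid(self, p=5):
        return WavelengthGrid(np.linspace(900, 1700, p))

    def test_valid_construction(self):
        s = SpectraSet(
            ids=["a", "b"],
            X=np.ones((2, 5)),
            grid=self._grid(),
            alcohol=np.array([4.0, 5.0]),
            klass=np.array(["craft", "industrial"], dtype=object),
        )
        assert s.n_samples == 2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SpectraSet(ids=["a", "a"], X=np.ones((2, 5)), grid=self._grid())

    def test_grid_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            SpectraSet(ids=["a"], X=np.ones((1, 4)), grid=self._grid(5))

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            SpectraSet(
                ids=["a"], X=np.ones((1, 5)), grid=self._grid(),
                klass=np.array(["lager"], dtype=object),
            )

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            SpectraSet(
                ids=["a"], X=np.ones((1, 5)), grid=self._grid(),
                alcohol=np.array([-1.0]),
            )

    def test_non_finite_absorbance_rejected(self):
        X = np.ones((1, 5))
        X[0, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            SpectraSet(ids=["a"], X=X, grid=self._grid())

    def test_subset_carries_targets(self, default_dataset):
        sub = default_dataset.subset(np.array([0, 5, 10]))
        assert sub.n_samples == 3
        assert sub.alcohol[1] == default_dataset.alcohol[5]
        assert sub.klass[2] == default_dataset.klass[10]

    def test_class_vocabulary(self):
        assert CLASSES == ("craft", "industrial", "nonfermented")


class TestCsvIO:
    def test_round_trip_preserves_everything(self, tmp_path, default_dataset):
        sub = default_dataset.subset(np.arange(6))
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        write_spectra_csv(sub, sp, tp)
        back = read_spectra_csv(sp, tp)
        assert back.ids == sub.ids
        np.testing.assert_allclose(back.X, sub.X, rtol=1e-9)
        np.testing.assert_allclose(
            back.grid.wavelengths, sub.grid.wavelengths, atol=0.005
        )
        np.testing.assert_allclose(back.alcohol, sub.alcohol)
        np.testing.assert_allclose(back.wort, sub.wort)
        assert list(back.klass) == list(sub.klass)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,900.00,901.00\na,1,2\na,3,4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_csv(p)

    def test_non_numeric_cell_is_located(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,900.00,901.00\na,1,x\n")
        with pytest.raises(ValueError, match="row 0, column '901.00'"):
            read_spectra_csv(p)

    def test_unsorted_wavelength_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,901.00,900.00\na,1,2\n")
        with pytest.raises(ValueError, match="sorted"):
            read_spectra_csv(p)

    def test_missing_target_id_rejected(self, tmp_path):
        sp = tmp_path / "s.csv"
        tp = tmp_path / "t.csv"
        sp.write_text("sample_id,900.00,901.00\na,1,2\nb,3,4\n")
        tp.write_text("sample_id,alcohol_vol_pct,wort_degP,class\na,4.0,10.0,craft\n")
        with pytest.raises(ValueError, match="missing sample id"):
            read_spectra_csv(sp, tp)

    def test_first_column_must_be_sample_id(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,900.00\na,1\n")
        with pytest.raises(ValueError, match="sample_id"):
            read_spectra_csv(p)
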