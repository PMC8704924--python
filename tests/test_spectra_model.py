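"""Container invariants and IO round trips for the spectra data model."""

import numpy as np
import pytest

import carotannot as ca
from carotannot.spectra_model import _dedupe_fragments


def _tiny_dataset():
    return ca.Dataset(
        peaks=[
            ca.ChromPeak("a", 5.0, 40.0, [
                ca.Ms2Spectrum(585.2, [ca.MzPeak(566.4), ca.MzPeak(549.0, 12.5)]),
                ca.Ms2Spectrum(413.7, [ca.MzPeak(301.0)]),
            ], percent_iii_ii=20.0),
            ca.ChromPeak("b", 7.5, 60.0, [
                ca.Ms2Spectrum(568.6, [ca.MzPeak(550.4, 4.9)]),
            ]),
        ],
        source_taxon="bacteria",
    )


class TestInvariants:
    @pytest.mark.parametrize("bad", [
        lambda: ca.MzPeak(-1.0),
        lambda: ca.MzPeak(100.0, 150.0),
        lambda: ca.Ms2Spectrum(-5.0),
        lambda: ca.Ms2Spectrum(100.0, [ca.MzPeak(500.0)]),   # fragment above precursor
        lambda: ca.ChromPeak("x", -1.0, 10.0, [ca.Ms2Spectrum(100.0)]),
        lambda: ca.ChromPeak("x", 1.0, 10.0, []),             # no spectrum
        lambda: ca.DadSpectrum(np.array([400.0, 400.0]), np.array([1.0, 2.0])),
        lambda: ca.DadSpectrum(np.array([400.0, 410.0]), np.array([1.0, np.inf])),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_duplicate_peak_ids_rejected(self):
        peak = ca.ChromPeak("a", 1.0, 10.0, [ca.Ms2Spectrum(100.0)])
        peak2 = ca.ChromPeak("a", 2.0, 10.0, [ca.Ms2Spectrum(100.0)])
        with pytest.raises(ValueError, match="unique"):
            ca.Dataset([peak, peak2])

    def test_area_budget_enforced(self):
        peaks = [ca.ChromPeak(str(i), float(i), 60.0, [ca.Ms2Spectrum(100.0)])
                 for i in range(2)]
        with pytest.raises(ValueError, match="100.5"):
            ca.Dataset(peaks)


class TestPeakTable:
    def test_round_trip(self, tmp_path):
        ds = _tiny_dataset()
        path = tmp_path / "peaks.csv"
        ca.write_peak_table(ds, path)
        back = ca.read_peak_table(path, source_taxon="bacteria")
        assert [p.peak_id for p in back.peaks] == ["a", "b"]
        pa = back.peak("a")
        assert pa.rt_min == 5.0 and pa.area_percent == 40.0
        assert pa.percent_iii_ii == 20.0
        assert pa.spectra[0].precursor_mz == 585.2
        assert pa.spectra[0].fragments[1].rel_intensity == 12.5
        assert back.peak("b").spectra[0].fragments[0].rel_intensity == 4.9

    def test_missing_column_names_expected_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("peak_id,rt_min\n1,2.0\n")
        with pytest.raises(ValueError, match="precursor_mz"):
            ca.read_peak_table(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("peak_id,rt_min,area_percent,precursor_mz,fragments\n"
                        "1,oops,1.0,500.0,\n")
        with pytest.raises(ValueError, match="row 2"):
            ca.read_peak_table(path)

    def test_duplicate_rows_merge_as_set_union(self, tmp_path):
        # oracle: union of token lists, de-duplicated by m/z within 0.01
        path = tmp_path / "dup.csv"
        path.write_text("peak_id,rt_min,area_percent,precursor_mz,fragments\n"
                        "1,2.0,10.0,500.0,480.0;462.0\n"
                        "1,2.0,10.0,500.0,462.0;408.0\n")
        ds = ca.read_peak_table(path)
        assert len(ds.peaks) == 1
        frags = ds.peaks[0].spectra[0].fragment_mzs
        assert sorted(frags) == sorted({480.0, 462.0, 408.0})

    def test_grouping_is_order_independent(self, tmp_path):
        header = "peak_id,rt_min,area_percent,precursor_mz,fragments\n"
        rows = ["1,2.0,10.0,500.0,480.0", "2,1.0,20.0,400.0,380.0",
                "1,2.0,10.0,450.0,430.0"]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        a.write_text(header + "\n".join(rows) + "\n")
        b.write_text(header + "\n".join(reversed(rows)) + "\n")
        da, db_ = ca.read_peak_table(a), ca.read_peak_table(b)
        assert [p.peak_id for p in da.peaks] == [p.peak_id for p in db_.peaks]
        for pa, pb in zip(da.peaks, db_.peaks):
            assert sorted(pa.precursor_mzs) == sorted(pb.precursor_mzs)

    def test_dedupe_keeps_known_intensity(self):
        merged = _dedupe_fragments([ca.MzPeak(550.4), ca.MzPeak(550.4, 4.9)])
        assert len(merged) == 1 and merged[0].rel_intensity == 4.9


class TestMgf:
    def test_round_trip_groups_by_title(self, tmp_path):
        ds = _tiny_dataset()
        path = tmp_path / "spectra.mgf"
        ca.write_mgf(ds, path)
        back = ca.read_mgf(path)
        assert [p.peak_id for p in back.peaks] == ["a", "b"]
        assert len(back.peak("a").spectra) == 2
        assert back.peak("a").spectra[0].precursor_mz == pytest.approx(585.2)
        assert back.peak("a").rt_min == pytest.approx(5.0)
        # fragment order preserved
        assert back.peak("a").spectra[0].fragment_mzs == [566.4, 549.0]

    def test_single_block(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text("BEGIN IONS\nTITLE=peak=4\nPEPMASS=568.6\n"
                        "476.4 10\n550.4 5\n458.4 3\n415.4 1\nEND IONS\n")
        ds = ca.read_mgf(path)
        assert len(ds.peaks) == 1
        assert len(ds.peaks[0].spectra) == 1
        assert len(ds.peaks[0].spectra[0].fragments) == 4

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            ds = ca.read_mgf(path)
        assert len(ds.peaks) == 0

    def test_block_without_fragments_retained(self, tmp_path):
        path = tmp_path / "nofrag.mgf"
        path.write_text("BEGIN IONS\nTITLE=peak=3\nPEPMASS=567.0\nEND IONS\n")
        ds = ca.read_mgf(path)
        assert len(ds.peaks[0].spectra[0].fragments) == 0

    def test_missing_pepmass_skipped_with_warning(self, tmp_path):
        path = tmp_path / "nomass.mgf"
        path.write_text("BEGIN IONS\nTITLE=peak=1\n100.0 1\nEND IONS\n"
                        "BEGIN IONS\nTITLE=peak=2\nPEPMASS=500.0\n400.0 1\nEND IONS\n")
        with pytest.warns(UserWarning, match="PEPMASS"):
            ds = ca.read_mgf(path)
        assert [p.peak_id for p in ds.peaks] == ["2"]


def test_dad_csv_round_trip(tmp_path):
    spec = ca.DadSpectrum(np.arange(300.0, 701.0, 2.0),
                          np.linspace(0.0, 1.0, 201))
    path = tmp_path / "dad.csv"
    ca.write_dad_csv(spec, path)
    back = ca.read_dad_csv(path)
    np.testing.assert_allclose(back.wavelengths, spec.wavelengths)
    np.testing.assert_allclose(back.absorbances, spec.absorbances)
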