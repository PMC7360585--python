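"""File format round-trips, LMD dataset selection, linearization, naming."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cytoharm import EventMatrix, read_fcs, read_table, \
    standardize_channels, write_fcs, write_lmd, write_table
from cytoharm.exceptions import (AmbiguousDateError, ChannelMappingError,
                                 CytoharmError, EmptyFCSError,
                                 FCSFormatError, FCSMetadataError)
from cytoharm.fcs_io import parse_fcs_date
from cytoharm.panels import PANEL1_CHANNEL_MAP

from conftest import D0, make_event_matrix


class TestRoundTrip:
    def test_values_names_meta_preserved(self, rng, tmp_path):
        em = make_event_matrix(rng, n_events=100,
                               channels=[f"ch{i}" for i in range(10)])
        path = tmp_path / "a.fcs"
        write_fcs(em, path)
        back = read_fcs(path)
        assert back.n_events == 100 and back.n_channels == 10
        assert back.channel_names == em.channel_names
        # float32 storage: relative error bounded by one ulp
        assert np.allclose(back.values, em.values, rtol=1e-6)
        assert back.meta["acquisition_date"] == D0
        assert back.meta["instrument_id"] == "NAVIOS-1"
        assert back.meta["sample_id"] == "S1"

    def test_write_refuses_zero_events(self, tmp_path):
        em = EventMatrix(np.empty((0, 2)), ["a", "b"])
        with pytest.raises(EmptyFCSError):
            write_fcs(em, tmp_path / "z.fcs")


class TestLMD:
    def test_last_dataset_returned_by_default(self, rng, tmp_path):
        first = make_event_matrix(rng, n_events=40)
        second = make_event_matrix(rng, n_events=170)
        path = tmp_path / "a.lmd"
        write_lmd([first, second], path)
        em = read_fcs(path)                     # default: last = FCS3.0
        assert em.n_events == 170
        assert em.meta["fcs_version"] == "FCS3.0"
        assert read_fcs(path, dataset="first").n_events == 40
        assert em.meta["vendor"] == "BC"        # dual dataset -> Beckman


class TestLinearization:
    def test_four_decade_log_channel(self, tmp_path):
        # stored value 512 on a 4-decade 1024-channel scale -> 10^(4*512/1024)
        em = EventMatrix(np.array([[512.0], [1023.0], [0.0]]), ["FL1"],
                         {"sample_id": "lin"})
        path = tmp_path / "log.fcs"
        write_fcs(em, path, datatype="I", pne=["4,0"])
        back = read_fcs(path)
        expected = 10.0 ** (4.0 * np.array([512, 1023, 0]) / 1024)
        assert np.allclose(back.values[:, 0], expected, rtol=1e-12)

    def test_float_channels_untouched(self, rng, tmp_path):
        em = make_event_matrix(rng)
        write_fcs(em, tmp_path / "f.fcs")
        assert np.allclose(read_fcs(tmp_path / "f.fcs").values, em.values,
                           rtol=1e-6)


class TestMalformedFiles:
    def test_bad_magic(self, rng, tmp_path):
        path = tmp_path / "bad.fcs"
        write_fcs(make_event_matrix(rng), path)
        data = bytearray(path.read_bytes())
        data[0:6] = b"NOTFCS"
        path.write_bytes(bytes(data))
        with pytest.raises(FCSFormatError):
            read_fcs(path)

    def test_zero_events_keyword(self, rng, tmp_path):
        path = tmp_path / "zero.fcs"
        write_fcs(make_event_matrix(rng, n_events=100), path)
        patched = path.read_bytes().replace(b"$TOT/100", b"$TOT/000")
        path.write_bytes(patched)
        with pytest.raises(EmptyFCSError):
            read_fcs(path)

    def test_missing_channel_name_keyword(self, rng, tmp_path):
        path = tmp_path / "nopn.fcs"
        write_fcs(make_event_matrix(rng), path)
        patched = path.read_bytes().replace(b"$P1N", b"$Q1N")
        path.write_bytes(patched)
        with pytest.raises(FCSMetadataError):
            read_fcs(path)


class TestDates:
    @pytest.mark.parametrize("text,expected", [
        ("2015-03-04", dt.date(2015, 3, 4)),
        ("04-MAR-2015", dt.date(2015, 3, 4)),
        ("4-Mar-2015", dt.date(2015, 3, 4)),
    ])
    def test_unambiguous_forms(self, text, expected):
        assert parse_fcs_date(text) == expected

    def test_numeric_day_month_rejected(self):
        # dd-mm vs mm-dd cannot be told apart; never guessed
        with pytest.raises(AmbiguousDateError):
            parse_fcs_date("03-04-2015")


class TestStandardizeChannels:
    def _em(self, names, values=None):
        v = values if values is not None else \
            np.arange(len(names) * 3, dtype=float).reshape(3, len(names))
        return EventMatrix(v, names, {"panel_id": "panel1"})

    def test_bc_and_bd_dialects_agree(self, rng):
        canon = list(PANEL1_CHANNEL_MAP.canonical_order)
        values = rng.uniform(10, 1e4, size=(50, len(canon)))
        bc = ["FS INT", "SS INT"] + [f"FL{i + 1} INT" for i in range(8)]
        bd = ["FSC-A", "SSC-A", "FITC-A", "PE-A", "PerCP-Cy5-5-A",
              "PE-Cy7-A", "APC-A", "APC-H7-A", "V450-A", "V500-A"]
        out_bc = standardize_channels(self._em(bc, values),
                                      PANEL1_CHANNEL_MAP)
        out_bd = standardize_channels(self._em(bd, values),
                                      PANEL1_CHANNEL_MAP)
        assert out_bc.channel_names == out_bd.channel_names == canon
        assert np.array_equal(out_bc.values, out_bd.values)

    def test_idempotent_and_bit_identical(self, rng):
        canon = list(PANEL1_CHANNEL_MAP.canonical_order)
        values = rng.uniform(10, 1e4, size=(20, len(canon)))
        em = self._em(canon, values)
        once = standardize_channels(em, PANEL1_CHANNEL_MAP)
        twice = standardize_channels(once, PANEL1_CHANNEL_MAP)
        assert np.array_equal(once.values, values)
        assert np.array_equal(twice.values, once.values)
        assert twice.channel_names == once.channel_names

    def test_unmatched_detectors_all_reported(self):
        names = ["FS INT", "SS INT", "MYSTERY1", "MYSTERY2"] \
            + [f"FL{i + 1} INT" for i in range(8)]
        with pytest.raises(ChannelMappingError) as err:
            standardize_channels(self._em(names), PANEL1_CHANNEL_MAP)
        assert "MYSTERY1" in str(err.value) and "MYSTERY2" in str(err.value)

    def test_time_channel_dropped_silently(self, rng):
        names = ["FS INT", "SS INT", "TIME"] + [f"FL{i + 1} INT"
                                                for i in range(8)]
        out = standardize_channels(self._em(names), PANEL1_CHANNEL_MAP)
        assert "TIME" not in out.channel_names


class TestCohortTableCSV:
    def test_round_trip_with_provenance(self, tmp_path):
        table = pd.DataFrame({
            "sample_id": ["a", "b", "c", "d", "e"],
            "instrument_id": ["I1"] * 5,
            "acquisition_date": [D0] * 5,
            "freq|T cells": np.linspace(20, 30, 5),
            "mfi|T cells|CD3": np.linspace(9e3, 1.1e4, 5),
        })
        table.attrs["corrections"] = ["batch"]
        path = tmp_path / "t.csv"
        write_table(table, path)
        back = read_table(path)
        assert back.attrs["corrections"] == ["batch"]
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True),
                                      check_dtype=False)

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(CytoharmError):
            write_table(pd.DataFrame(), tmp_path / "e.csv")
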