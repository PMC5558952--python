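"""Tucson/RWL and long-form table round trips, anchoring and validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrocarbon.ringio import (
    RingSeries,
    RwlFormatError,
    read_rwl,
    read_series_table,
    write_rwl,
    write_series_table,
)


def make_series(widths, last_year=2000, tree="T1", radius="r1"):
    return RingSeries(
        tree_id=tree, radius_id=radius, widths=np.asarray(widths, float),
        last_year=last_year,
    )


class TestRingSeries:
    def test_year_anchoring(self):
        s = make_series([1.0, 2.0, 3.0], last_year=2000)
        assert s.first_year == 1998
        assert list(s.years) == [1998, 1999, 2000]
        assert s.n_years == 3

    @pytest.mark.parametrize(
        "widths", [[], [-0.5], [np.nan], [np.inf]], ids=["empty", "neg", "nan", "inf"]
    )
    def test_invalid_widths_rejected(self, widths):
        with pytest.raises(ValueError):
            make_series(widths)

    def test_zero_width_encodes_wedge_ring(self):
        s = make_series([1.0, 0.0, 1.0])
        assert s.widths[1] == 0.0


class TestRwl:
    def test_unit_conversion_001mm(self, tmp_path):
        # 150 in the 0.01 mm dialect is a 1.50 mm ring
        path = tmp_path / "a.rwl"
        path.write_text("T1_r1   1998   150   150   150   999\n")
        (series,) = read_rwl(path)
        assert np.allclose(series.widths, [1.5, 1.5, 1.5])
        assert series.last_year == 2000

    def test_decade_break_anchoring(self, tmp_path):
        # hand-written per the decadal layout: a 1998-start series breaks
        # to a new line at the decade boundary 2000
        path = tmp_path / "b.rwl"
        path.write_text(
            "T1_r1   1998   120   130\n"
            "T1_r1   2000   140   999\n"
        )
        (series,) = read_rwl(path)
        assert np.allclose(series.widths, [1.2, 1.3, 1.4])
        assert series.first_year == 1998
        assert series.last_year == 2000

    def test_millimeter_dialect(self, tmp_path):
        path = tmp_path / "c.rwl"
        path.write_text("T1_r1   2000  1500  1500 -9999\n")
        (series,) = read_rwl(path)
        assert np.allclose(series.widths, [1.5, 1.5])
        assert series.resolution_mm == 0.001

    @given(
        n=st.integers(1, 400),
        last_year=st.integers(1500, 2025),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, n, last_year, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        widths = np.round(rng.uniform(0, 12, size=n), 2)
        s = make_series(widths, last_year=last_year)
        path = tmp_path_factory.mktemp("rwl") / "rt.rwl"
        write_rwl([s], path)
        (back,) = read_rwl(path)
        assert back.last_year == s.last_year
        np.testing.assert_array_equal(back.widths, s.widths)

    def test_stop_marker_collision_switches_dialect(self, tmp_path):
        # a genuine 9.99 mm ring would encode to the 999 stop marker;
        # the writer must switch to the -9999 dialect and still round-trip
        s = make_series([1.0, 9.99, 9.99])
        path = tmp_path / "d.rwl"
        write_rwl([s], path)
        assert "-9999" in path.read_text()
        (back,) = read_rwl(path)
        np.testing.assert_array_equal(back.widths, s.widths)

    def test_255_year_series_line_count(self, tmp_path):
        # starting 1746 and ending 2000: a partial first line (1746-1749),
        # 25 full decades (1750-1999), and a final line carrying the year
        # 2000 value plus the stop marker = 27 lines
        widths = np.full(255, 1.0)
        s = make_series(widths, last_year=2000)
        path = tmp_path / "e.rwl"
        write_rwl([s], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 27
        (back,) = read_rwl(path)
        assert back.n_years == 255

    def test_no_silent_drops(self, tmp_path, rng):
        series = [
            make_series(np.round(rng.uniform(0, 5, rng.integers(5, 60)), 2),
                        tree=f"T{i}", radius="r1")
            for i in range(6)
        ]
        path = tmp_path / "f.rwl"
        write_rwl(series, path)
        tokens = path.read_text().split()
        n_values = sum(
            1 for t in tokens if t.lstrip("-").isdigit() and int(t) not in (999, -9999)
            and not t.startswith("T")
        )
        # every line contributes its year token as well
        n_lines = len(path.read_text().splitlines())
        parsed = read_rwl(path)
        assert sum(s.n_years for s in parsed) == n_values - n_lines

    def test_empty_collection_empty_file(self, tmp_path):
        path = tmp_path / "g.rwl"
        write_rwl([], path)
        assert path.read_text() == ""
        assert read_rwl(path) == []

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "h.rwl"
        path.write_text("T1_r1   2000   150  -150   999\n")
        with pytest.raises(ValueError, match="negative width"):
            read_rwl(path)

    def test_malformed_decade_sequence(self, tmp_path):
        path = tmp_path / "i.rwl"
        path.write_text(
            "T1_r1   1990   120   130   140   150   160   170   180   190   200   210\n"
            "T1_r1   2010   140   999\n"
        )
        with pytest.raises(RwlFormatError, match="line 2"):
            read_rwl(path)

    def test_unterminated_series_rejected(self, tmp_path):
        path = tmp_path / "j.rwl"
        path.write_text(
            "T1_r1   2000   150   150   150   150   150"
            "   150   150   150   150   150\n"
        )
        with pytest.raises(RwlFormatError, match="stop marker"):
            read_rwl(path)

    def test_width_overflow_rejected(self, tmp_path):
        s = make_series([10000.0])
        with pytest.raises(ValueError, match="overflow"):
            write_rwl([s], tmp_path / "k.rwl")


class TestSeriesTable:
    def test_basic_read(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "tree_id,species,radius_id,year,width_mm\n"
            "T1,G_glabra,r1,2000,1.0\n"
            "T1,G_glabra,r1,2001,2.0\n"
            "T1,G_glabra,r1,2002,3.0\n"
        )
        (s,) = read_series_table(path)
        assert s.last_year == 2002
        assert s.species == "G_glabra"
        np.testing.assert_array_equal(s.widths, [1.0, 2.0, 3.0])

    def test_row_order_invariance(self, tmp_path):
        header = "tree_id,species,radius_id,year,width_mm\n"
        rows = [f"T1,S,r1,{2000 + i},{w}\n" for i, w in enumerate([1.0, 2.0, 3.0])]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        a.write_text(header + "".join(rows))
        b.write_text(header + "".join(reversed(rows)))
        (sa,) = read_series_table(a)
        (sb,) = read_series_table(b)
        np.testing.assert_array_equal(sa.widths, sb.widths)
        assert sa.last_year == sb.last_year

    def test_round_trip(self, tmp_path, rng):
        series = [
            make_series(np.round(rng.uniform(0, 5, 30), 2), tree="T1", radius=f"r{i}")
            for i in range(1, 4)
        ]
        path = tmp_path / "rt.csv"
        write_series_table(series, path)
        back = read_series_table(path)
        assert len(back) == 3
        for orig, new in zip(series, sorted(back, key=lambda s: s.radius_id)):
            np.testing.assert_array_equal(orig.widths, new.widths)
            assert orig.last_year == new.last_year

    def test_year_gap_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "tree_id,species,radius_id,year,width_mm\n"
            "T1,S,r1,2000,1.0\nT1,S,r1,2003,2.0\n"
        )
        with pytest.raises(ValueError, match=r"missing years \[2001, 2002\]"):
            read_series_table(path)

    def test_duplicate_year_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "tree_id,species,radius_id,year,width_mm\n"
            "T1,S,r1,2000,1.0\nT1,S,r1,2000,2.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_series_table(path)
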