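"""Damage-database storage, I/O, interpolation and the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tlksim as t
from tlksim.errors import RangeError, ValidationError
from tlksim.yield_db import FixtureParams


def small_table():
    return t.YieldTable(
        energies_ev=np.array([1e3, 1e5]),
        oxygens_pct=np.array([1.0, 21.0]),
        sdsb=np.array([[10.0, 12.0], [4.0, 5.0]]),
        cdsb=np.array([[20.0, 22.0], [3.0, 4.0]]),
    )


class TestIO:
    def test_minimal_rectangular_grid_roundtrip(self, tmp_path):
        tab = small_table()
        path = tmp_path / "db.csv"
        t.write_yield_table(tab, path)
        back = t.read_yield_table(path)
        assert back.energies_ev.tolist() == [1e3, 1e5]
        assert back.oxygens_pct.tolist() == [1.0, 21.0]
        np.testing.assert_array_equal(back.sdsb, tab.sdsb)
        np.testing.assert_array_equal(back.cdsb, tab.cdsb)

    def test_nonrectangular_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "energy_ev,oxygen_pct,sdsb_per_cell_gy,cdsb_per_cell_gy\n"
            "1000,1,10,20\n1000,21,12,22\n100000,1,4,3\n"
        )
        with pytest.raises(ValidationError, match="not rectangular"):
            t.read_yield_table(path)

    def test_duplicate_grid_point_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "energy_ev,oxygen_pct,sdsb_per_cell_gy,cdsb_per_cell_gy\n"
            "1000,1,10,20\n1000,1,10,20\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            t.read_yield_table(path)

    def test_negative_yield_rejected_naming_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(
            "energy_ev,oxygen_pct,sdsb_per_cell_gy,cdsb_per_cell_gy\n"
            "1000,1,10,20\n1000,21,-1,22\n100000,1,4,3\n100000,21,5,4\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            t.read_yield_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("energy_ev,oxygen_pct,sdsb_per_cell_gy\n1000,1,10\n")
        with pytest.raises(ValidationError, match="cdsb_per_cell_gy"):
            t.read_yield_table(path)


class TestInterpolation:
    def test_exact_at_grid_nodes(self, table):
        for i in (0, 5, len(table.energies_ev) - 1):
            for j in (0, 3, len(table.oxygens_pct) - 1):
                s, c = table.interpolate(table.energies_ev[i], table.oxygens_pct[j])
                assert s == pytest.approx(table.sdsb[i, j], rel=1e-12)
                assert c == pytest.approx(table.cdsb[i, j], rel=1e-12)

    def test_log_energy_midpoint_is_arithmetic_mean(self):
        tab = small_table()
        e_mid = 10 ** ((3 + 5) / 2)  # geometric mean of the energy nodes
        s, c = tab.interpolate(e_mid, 1.0)
        assert s == pytest.approx((10.0 + 4.0) / 2, rel=1e-12)
        assert c == pytest.approx((20.0 + 3.0) / 2, rel=1e-12)

    def test_matches_nested_1d_interpolation_oracle(self, table):
        # brute-force oracle: interpolate along log-energy at each oxygen
        # level, then along log-oxygen
        rng = np.random.default_rng(42)
        loge = np.log10(table.energies_ev)
        logo = np.log10(table.oxygens_pct)
        for _ in range(50):
            qe = 10 ** rng.uniform(loge[0], loge[-1])
            qo = 10 ** rng.uniform(logo[0], logo[-1])
            s, c = table.interpolate(qe, qo)
            for arr, got in ((table.sdsb, s), (table.cdsb, c)):
                per_ox = [
                    np.interp(np.log10(qe), loge, arr[:, j])
                    for j in range(logo.size)
                ]
                want = np.interp(np.log10(qo), logo, per_ox)
                assert got == pytest.approx(want, rel=1e-12)

    def test_out_of_hull_query_rejected(self, table):
        with pytest.raises(RangeError):
            table.interpolate(10.0, 21.0)
        with pytest.raises(RangeError):
            table.interpolate(1e6, 0.0001)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        loge=st.floats(min_value=np.log10(50.0), max_value=np.log10(6e6)),
        logo=st.floats(min_value=-3.0, max_value=2.0),
    )
    def test_interpolated_yields_within_node_bounds(self, loge, logo):
        # bilinear interpolation of non-negative monotone-bounded data stays
        # within the enclosing cell's min/max
        tab = t.generate_fixture_table()
        s, c = tab.interpolate(10**loge, 10**logo)
        assert 0 <= s <= tab.sdsb.max()
        assert 0 <= c <= tab.cdsb.max()


class TestFixtureGenerator:
    def test_high_energy_plateau_near_asymptote(self, table):
        p = FixtureParams()
        s, c = table.interpolate(1e6, 21.0)
        plateau = p.y_inf * p.oxygen_factor(21.0)
        assert (s + c) == pytest.approx(plateau, rel=0.05)

    def test_low_energy_rise_is_monotone(self, table):
        tot = lambda e: sum(table.interpolate(e, 21.0))
        assert tot(1e3) > tot(1e5) > 0.99 * tot(1e6)

    def test_hypoxia_suppresses_yields_at_every_energy(self, table):
        for e in table.energies_ev:
            assert sum(table.interpolate(e, 0.001)) < sum(table.interpolate(e, 21.0))

    def test_oxygen_factor_strictly_increasing(self):
        p = FixtureParams()
        c = np.array([0.001, 0.01, 0.1, 1, 10, 21, 100])
        g = p.oxygen_factor(c)
        assert np.all(np.diff(g) > 0)
        assert g[-1] == pytest.approx(1.0, abs=0.01)
        assert g[0] == pytest.approx(1 / p.m_oxygen, rel=0.01)

    def test_cdsb_fraction_grows_at_low_energy_and_low_oxygen(self, table):
        frac = lambda e, o: table.interpolate(e, o)[1] / sum(table.interpolate(e, o))
        assert frac(1e3, 21.0) > frac(1e6, 21.0)
        assert frac(1e6, 0.001) > frac(1e6, 21.0)

    def test_nonpositive_shape_parameters_rejected(self):
        with pytest.raises(ValidationError):
            FixtureParams(y_inf=-1.0)
        with pytest.raises(ValidationError):
            FixtureParams(slope=0.0)

    def test_oxygen_zero_stored_as_anoxic_floor(self):
        tab = t.generate_fixture_table(oxygens_pct=[0.0, 21.0])
        assert tab.oxygens_pct[0] == pytest.approx(0.001)


class TestValidation:
    def test_unsorted_energies_rejected(self):
        with pytest.raises(ValidationError):
            t.YieldTable(
                energies_ev=np.array([1e5, 1e3]),
                oxygens_pct=np.array([1.0, 21.0]),
                sdsb=np.ones((2, 2)),
                cdsb=np.ones((2, 2)),
            )

    def test_negative_yield_rejected(self):
        with pytest.raises(ValidationError):
            t.YieldTable(
                energies_ev=np.array([1e3, 1e5]),
                oxygens_pct=np.array([1.0, 21.0]),
                sdsb=-np.ones((2, 2)),
                cdsb=np.ones((2, 2)),
            )
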