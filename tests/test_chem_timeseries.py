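import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipdenit.chem_timeseries import (
    ChemSeries,
    Phase,
    SupplementationEvent,
    default_phases,
    net_change,
    phase_balance,
    rate,
    read_chem_table,
)

from conftest import make_series


def brute_force_flows(days, values, events, start, end):
    """Independent oracle: walk every inter-breakpoint segment (all
    measurement days plus event days) summing declines and rises."""
    bps = sorted(
        set([start, end])
        | {d for d in days if start < d < end}
        | {e.day for e in events if start <= e.day < end}
    )
    vals = np.interp(bps, days, values)
    added = {b: 0.0 for b in bps}
    for e in events:
        if start <= e.day < end:
            added[e.day] += e.amount_uM
    cons = prod = 0.0
    for i in range(len(bps) - 1):
        s = vals[i] + added[bps[i]]
        diff = s - vals[i + 1]
        if diff > 0:
            cons += diff
        else:
            prod -= diff
    return cons, prod


class TestChemSeries:
    def test_construction_and_interp(self):
        s = make_series("acetate", [0, 3, 6], [400, 200, 0])
        assert s.interp(1.5) == pytest.approx(300.0)
        assert not s.unitless

    def test_days_must_strictly_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_series("acetate", [0, 3, 3], [1, 2, 3])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_series("CO2", [0, 1], [0, -5])

    def test_ph_is_unitless_and_range_checked(self):
        s = make_series("pH", [0, 16], [4.4, 5.5])
        assert s.unitless
        with pytest.raises(ValueError, match="pH"):
            make_series("pH", [0, 1], [4.4, 15.0])


class TestReadChemTable:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "chem.csv"
        p.write_text(
            textwrap.dedent(
                """\
                treatment,replicate,day,analyte,value
                13C,1,0,acetate,400
                13C,1,3,acetate,200
                13C,1,6,acetate,0
                """
            )
        )
        series, events = read_chem_table(p)
        assert len(series) == 1 and len(series[0].days) == 3
        assert events == []

    def test_duplicate_day_reports_row(self, tmp_path):
        p = tmp_path / "chem.csv"
        p.write_text(
            "treatment,replicate,day,analyte,value\n"
            "13C,1,0,acetate,400\n13C,1,0,acetate,390\n"
        )
        with pytest.raises(ValueError, match=r"rows \[1, 2\]"):
            read_chem_table(p)

    def test_ph_value_accepted_as_unitless(self, tmp_path):
        p = tmp_path / "chem.csv"
        p.write_text(
            "treatment,replicate,day,analyte,value\n"
            "13C,1,0,pH,4.4\n13C,1,6,pH,5.5\n"
        )
        series, _ = read_chem_table(p)
        assert series[0].unitless and series[0].values[0] == 4.4

    def test_events_round_trip(self, tmp_path):
        chem = tmp_path / "chem.csv"
        chem.write_text(
            "treatment,replicate,day,analyte,value\n13C,1,0,nitrate,300\n"
            "13C,1,6,nitrate,0\n"
        )
        ev = tmp_path / "events.csv"
        ev.write_text("treatment,analyte,day,amount_uM\n13C,nitrate,6,600\n")
        _, events = read_chem_table(chem, ev)
        assert events[0].amount_uM == 600.0


class TestNetChange:
    def test_constant_series_zero(self):
        s = make_series("acetate", [0, 3, 6], [100, 100, 100])
        nc = net_change(s, [], Phase("I", 0, 6))
        assert nc.net == nc.consumption == nc.production == 0.0

    def test_refeed_gross_consumption(self):
        # 300 down to 0 by day 6, +600 refeed, down to 0 by day 15
        s = make_series("acetate", [0, 6, 15], [300, 0, 0])
        ev = [SupplementationEvent("13C", "acetate", 6.0, 600.0)]
        nc = net_change(s, ev, Phase("all", 0, 15))
        assert nc.consumption == pytest.approx(900.0)
        assert nc.net == pytest.approx(-900.0)

    def test_cumulative_nitrate_supplementation(self):
        # endogenous 390 plus two 600 µM refeeds, all consumed
        s = make_series("nitrate", [0, 6, 11, 15], [390, 0, 0, 0])
        evs = [
            SupplementationEvent("13C", "nitrate", 6.0, 600.0),
            SupplementationEvent("13C", "nitrate", 11.0, 600.0),
        ]
        nc = net_change(s, evs, Phase("all", 0, 15))
        assert nc.consumption == pytest.approx(1590.0)

    def test_matches_brute_force_oracle_with_refeed(self):
        days = [0, 2, 4, 6, 8, 10]
        vals = [350, 250, 120, 0, 310, 150]
        s = make_series("acetate", days, vals)
        evs = [SupplementationEvent("13C", "acetate", 6.0, 400.0)]
        nc = net_change(s, evs, Phase("w", 0, 10))
        cons, prod = brute_force_flows(
            np.array(days, float), np.array(vals, float), evs, 0.0, 10.0
        )
        assert nc.consumption == pytest.approx(cons)
        assert nc.production == pytest.approx(prod)

    def test_phase_outside_data_range_errors(self):
        s = make_series("acetate", [0, 6], [100, 0])
        with pytest.raises(ValueError, match="outside data range"):
            net_change(s, [], Phase("x", 0, 10))

    def test_event_outside_measurements_errors(self):
        s = make_series("acetate", [0, 6], [100, 0])
        ev = [SupplementationEvent("13C", "acetate", 8.0, 100.0)]
        with pytest.raises(ValueError, match="bracketing"):
            net_change(s, ev, Phase("x", 0, 6))

    def test_net_is_production_minus_consumption(self):
        s = make_series("N2O", [0, 3, 6, 9], [0, 12, 12, 5])
        for phase in (Phase("a", 0, 6), Phase("b", 6, 9), Phase("c", 0, 9)):
            nc = net_change(s, [], phase)
            assert nc.net == pytest.approx(nc.production - nc.consumption)

    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=1000), min_size=4, max_size=8
        ),
        frac=st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decline_additivity(self, vals, frac):
        """For declining series, consumption over a partition of the range
        sums to the whole-range consumption, with the cut anywhere."""
        vals = sorted(vals, reverse=True)
        days = np.arange(len(vals), dtype=float)
        s = make_series("acetate", days, vals)
        lo, hi = 0.0, float(days[-1])
        split = lo + frac * (hi - lo)
        whole = net_change(s, [], Phase("w", lo, hi)).consumption
        parts = (
            net_change(s, [], Phase("a", lo, split)).consumption
            + net_change(s, [], Phase("b", split, hi)).consumption
        )
        assert parts == pytest.approx(whole, abs=1e-6)

    def test_zero_events_conservation_for_decline(self):
        s = make_series("acetate", [0, 2, 5, 9], [420, 300, 150, 30])
        nc = net_change(s, [], Phase("w", 0, 9))
        assert nc.consumption + s.values[-1] == pytest.approx(s.values[0])


class TestPhaseBalance:
    def test_reproduces_study_phase1_deltas(self, table2_phase1_series, phase_i):
        b = phase_balance(table2_phase1_series, [], phase_i)
        assert b.delta_acetate == pytest.approx(111.0)
        assert b.delta_no3_n == pytest.approx(215.0)
        assert b.delta_co2_c == pytest.approx(124.0)
        assert b.delta_n2o_n == pytest.approx(25.0)
        assert b.delta_n2_n == pytest.approx(71.0)
        assert b.delta_nh4_n == pytest.approx(8.0)

    def test_all_constant_series_zero_deltas(self, phase_i):
        series = {
            a: make_series(a, [0, 6], [50, 50])
            for a in ("acetate", "nitrate", "CO2", "N2O")
        }
        with pytest.warns(UserWarning):
            b = phase_balance(series, [], phase_i)
        assert b.delta_acetate == b.delta_co2_c == b.delta_n2o_n == 0.0

    def test_n2o_counts_two_n_per_molecule(self, phase_i):
        series = {
            "acetate": make_series("acetate", [0, 6], [100, 0]),
            "nitrate": make_series("nitrate", [0, 6], [100, 0]),
            "CO2": make_series("CO2", [0, 6], [0, 100]),
            "N2O": make_series("N2O", [0, 6], [0, 10]),
        }
        with pytest.warns(UserWarning):
            b = phase_balance(series, [], phase_i)
        assert b.delta_n2o_n == pytest.approx(20.0)

    def test_missing_mandatory_analyte_errors(self, phase_i):
        series = {"acetate": make_series("acetate", [0, 6], [100, 0])}
        with pytest.raises(ValueError, match="nitrate"):
            phase_balance(series, [], phase_i)


class TestRate:
    def test_constant_series_zero_rate(self):
        s = make_series("CO2", [0, 3, 6], [10, 10, 10])
        assert rate(s, [], (0, 6)).net == 0.0

    def test_linear_decline_rate(self):
        s = make_series("acetate", [0, 6], [120, 0])
        assert rate(s, [], (0, 6)).consumption == pytest.approx(20.0)

    def test_refeed_rate_matches_oracle(self):
        days = [0, 3, 6, 9, 12]
        vals = [300, 150, 0, 200, 0]
        s = make_series("acetate", days, vals)
        evs = [SupplementationEvent("13C", "acetate", 6.0, 400.0)]
        r = rate(s, evs, (0, 12))
        cons, _ = brute_force_flows(
            np.array(days, float), np.array(vals, float), evs, 0.0, 12.0
        )
        assert r.consumption == pytest.approx(cons / 12.0)

    def test_zero_length_window_errors(self):
        s = make_series("acetate", [0, 6], [120, 0])
        with pytest.raises(ValueError):
            rate(s, [], (3, 3))


def test_default_phases_match_study_layout():
    phases = default_phases((0, 6, 15))
    assert [(p.name, p.start_day, p.end_day) for p in phases] == [
        ("I", 0, 6),
        ("II", 6, 15),
    ]
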