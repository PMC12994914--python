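import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from insom.legacy import (
    brown_compliance,
    circadian_potential,
    correlate,
    ferguson_label,
    legacy_metrics,
    nve_probability,
    nvrd_daily,
    nvrd_series,
    well_compliance,
)
from insom.scenarios import build_sleep_schedule
from insom.units import K_MEL, R_EML, MelanopicIrradianceSeries


def eml_series(eml_by_hour, days=1, dt=60.0):
    """Series whose EML equals ``eml_by_hour(h)`` at every sample."""
    t = np.arange(0.0, days * 86400.0, dt)
    h = (t / 3600.0) % 24.0
    eml = np.asarray([eml_by_hour(x) for x in h], dtype=float)
    values = eml / R_EML * K_MEL
    return MelanopicIrradianceSeries(t, values)


def edi_series(edi_by_hour, days=1, dt=60.0):
    t = np.arange(0.0, days * 86400.0, dt)
    h = (t / 3600.0) % 24.0
    edi = np.asarray([edi_by_hour(x) for x in h], dtype=float)
    return MelanopicIrradianceSeries(t, edi * K_MEL)


class TestNVE:
    @pytest.mark.parametrize("e, expected", [
        (960.0, 100.0), (210.0, 0.0), (585.0, 50.0),
        (0.0, 0.0), (5000.0, 100.0),
    ])
    def test_printed_anchors_and_linearity(self, e, expected):
        assert nve_probability(e) == pytest.approx(expected)

    def test_linear_formula_between_thresholds(self):
        for e in (300.0, 500.0, 750.0, 900.0):
            assert nve_probability(e) == pytest.approx(100.0 * e / 750.0 - 28.0)

    @given(st.floats(min_value=0, max_value=5000),
           st.floats(min_value=0, max_value=5000))
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        pa, pb = nve_probability(lo), nve_probability(hi)
        assert 0.0 <= pa <= pb <= 100.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            nve_probability(-1.0)


class TestCircadianPotential:
    def test_constant_saturating_light(self):
        # constant 960 lx D55-equivalent everywhere → CP 100 in all periods
        t = np.arange(0.0, 86400.0, 60.0)
        s = MelanopicIrradianceSeries(t, np.full_like(t, 960.0 * K_MEL))
        for per in ("resetting", "alerting", "avoidance"):
            assert circadian_potential(s, per) == pytest.approx(100.0)

    def test_darkness(self):
        t = np.arange(0.0, 86400.0, 60.0)
        s = MelanopicIrradianceSeries(t, np.zeros_like(t))
        assert circadian_potential(s, "resetting") == 0.0

    def test_half_time_at_each_threshold(self):
        # resetting period 06–10: half at 960 lx (100 %), half at 210 lx (0 %)
        def edi(h):
            if 6.0 <= h < 8.0:
                return 960.0
            if 8.0 <= h < 10.0:
                return 210.0
            return 0.0
        s = edi_series(edi)
        assert circadian_potential(s, "resetting") == pytest.approx(50.0)

    def test_unknown_period_rejected(self):
        t = np.arange(0.0, 86400.0, 60.0)
        with pytest.raises(ValueError):
            circadian_potential(MelanopicIrradianceSeries(t, np.zeros_like(t)),
                                "midnight")


class TestNvrd:
    def _day(self, lx, hours, dt=360.0):
        n = int(86400.0 / dt)
        e = np.zeros(n)
        h = np.arange(n) * dt / 3600.0
        e[(h >= 9.0) & (h < 9.0 + hours)] = lx
        return e

    def test_calibration_anchor(self):
        """824 lx D65 sustained 5 h on the 6-min grid scores exactly 4.2."""
        assert nvrd_daily(self._day(824.0, 5.0)) == pytest.approx(4.2)

    def test_dark_day_is_zero(self):
        assert nvrd_daily(np.zeros(240)) == 0.0

    def test_monotone_in_duration_and_level(self):
        assert nvrd_daily(self._day(824.0, 10.0)) > \
            nvrd_daily(self._day(824.0, 5.0))
        assert nvrd_daily(self._day(1600.0, 5.0)) > \
            nvrd_daily(self._day(824.0, 5.0))

    def test_wrong_grid_rejected(self):
        with pytest.raises(ValueError):
            nvrd_daily(np.zeros(1440), dt_s=60.0)

    def test_series_wrapper_matches_daily(self):
        t = np.arange(0.0, 86400.0, 360.0)
        h = (t / 3600.0) % 24.0
        photopic = np.where((h >= 9.0) & (h < 14.0), 824.0, 0.0)
        s = MelanopicIrradianceSeries(t, photopic * K_MEL, photopic=photopic)
        assert nvrd_series(s)[0] == pytest.approx(4.2)


class TestWell:
    def test_bright_all_day_meets_both_tiers(self):
        s = eml_series(lambda h: 300.0)
        assert well_compliance(s, "150EML") == 100.0
        assert well_compliance(s, "250EML") == 100.0

    def test_darkness(self):
        s = eml_series(lambda h: 0.0)
        assert well_compliance(s, "150EML") == 0.0
        assert well_compliance(s, "250EML") == 0.0
        assert well_compliance(s, "residential") == 100.0

    def test_midday_block_tier_rule(self):
        # EML 200 from 11:00–16:00 only: tier 1 (>150, ≥4 h starting ≤ noon)
        # is met; tier 2 (>250) is not
        s = eml_series(lambda h: 200.0 if 11.0 <= h < 16.0 else 0.0)
        assert well_compliance(s, "150EML") == 100.0
        assert well_compliance(s, "250EML") == 0.0

    def test_block_starting_after_noon_fails(self):
        s = eml_series(lambda h: 400.0 if 13.0 <= h < 18.0 else 0.0)
        assert well_compliance(s, "150EML") == 0.0

    def test_evening_light_breaks_residential(self):
        s = eml_series(lambda h: 80.0 if h >= 21.0 else 0.0)
        assert well_compliance(s, "residential") == 0.0

    def test_fraction_mode(self):
        # half the 06–18 qualifying window above threshold
        s = eml_series(lambda h: 300.0 if 6.0 <= h < 12.0 else 0.0)
        assert well_compliance(s, "250EML", mode="fraction") == \
            pytest.approx(50.0)


class TestBrown:
    def test_ideal_day_full_compliance(self, scheduled):
        s = edi_series(lambda h: 300.0 if 6.0 <= h < 21.0 else 0.0)
        out = brown_compliance(s, scheduled)
        assert out == {"daytime": 100.0, "nighttime": 100.0, "sleep": 100.0}

    def test_prebed_light_breaks_nighttime(self, scheduled):
        # 20 lx melanopic EDI in the 3 h before midnight bedtime
        s = edi_series(lambda h: 300.0 if 6.0 <= h < 21.0 else 20.0)
        out = brown_compliance(s, scheduled)
        assert out["nighttime"] == 0.0
        assert out["daytime"] == 100.0

    def test_boundary_value_counts_as_met(self, scheduled):
        s = edi_series(lambda h: 250.0 if 6.0 <= h < 21.0 else 0.0)
        assert brown_compliance(s, scheduled)["daytime"] == 100.0

    def test_lit_sleep_breaks_sleep_compliance(self, scheduled):
        s = edi_series(lambda h: 5.0 if h < 6.0 else 300.0)
        out = brown_compliance(s, scheduled)
        assert out["sleep"] == 0.0


class TestFerguson:
    @pytest.mark.parametrize("r, label", [
        (0.1, "not practically significant"),
        (0.2, "practically significant"),
        (0.49, "practically significant"),
        (0.5, "moderate"),
        (0.6, "moderate"),
        (0.8, "strong"),
        (-0.98, "strong"),
        (0.0, "not practically significant"),
    ])
    def test_labels(self, r, label):
        assert ferguson_label(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ferguson_label(1.2)


class TestCorrelate:
    def _tables(self, x, y):
        keys = pd.DataFrame({
            "view": [f"v{i}" for i in range(len(x))],
            "scenario": "daylight", "season": "winter",
        })
        legacy = keys.assign(nvRD=x)
        insom = keys.assign(KSS=y)
        return legacy, insom

    def test_identity_is_r_one(self):
        x = np.arange(10.0)
        table = correlate(*self._tables(x, x))
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_negative_affine_is_r_minus_one(self):
        x = np.arange(10.0)
        table = correlate(*self._tables(x, -2.0 * x + 7.0))
        assert table.loc[0, "r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        table = correlate(*self._tables(x, y))
        xm, ym = x - x.mean(), y - y.mean()
        oracle = np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2))
        assert table.loc[0, "r"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged_missing(self):
        x = np.arange(10.0)
        table = correlate(*self._tables(np.full(10, 3.0), x))
        assert np.isnan(table.loc[0, "r"])
        assert table.loc[0, "effect_size"] == "undefined"

    def test_too_few_units_rejected(self):
        x = np.arange(2.0)
        with pytest.raises(ValueError):
            correlate(*self._tables(x, x))


def test_legacy_metrics_bundle(scheduled):
    s = edi_series(lambda h: 300.0 if 6.0 <= h < 21.0 else 0.0, days=2)
    out = legacy_metrics(s, scheduled, meta={"view": "front"})
    assert out.nvrd_mean > 0
    assert set(out.cp) == {"resetting", "alerting", "avoidance"}
    assert out.brown["daytime"] == 100.0
    frame = out.to_frame()
    assert {"metric", "period", "value"} <= set(frame.columns)
    assert (frame["view"] == "front").all()
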