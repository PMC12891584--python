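import numpy as np
import pytest

from alanphen.alan import AnnualAlanSeries, day_length
from alanphen.models import (
    DEFAULT_BOUNDS,
    ModelParams,
    SenescenceModelSpec,
    lud_anomaly,
    param_names,
    photoperiod_response,
    predict_dfs,
    spring_summer_mean_temp,
)

from conftest import synthetic_temp_year


class TestSpecAndParams:
    def test_param_counts(self):
        # CDD=2, DM=5, SIAM=6, DMT=6; +1 with ALAN
        for family, count in [("CDD", 2), ("DM", 5), ("SIAM", 6), ("DMT", 6)]:
            assert SenescenceModelSpec(family).param_count == count
            assert SenescenceModelSpec(family, alan_enabled=True).param_count == count + 1

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            SenescenceModelSpec("XYZ")

    def test_bounds_enforced(self):
        spec = SenescenceModelSpec("CDD")
        with pytest.raises(ValueError, match="outside bounds"):
            ModelParams(spec, {"t_th": 60.0, "cdd_th": 100.0})

    def test_missing_param(self):
        spec = SenescenceModelSpec("DM")
        with pytest.raises(ValueError, match="missing"):
            ModelParams(spec, {"t_b": 10.0})

    def test_vector_round_trip(self):
        spec = SenescenceModelSpec("SIAM", alan_enabled=True)
        vals = {"t_b": 18.0, "p_s": 13.0, "x": 1.2, "y": 0.4, "a": 55.0, "b": -2.0, "k": 1.5}
        p = ModelParams(spec, vals)
        p2 = ModelParams.from_vector(spec, p.to_vector())
        assert p2.values == p.values
        assert param_names(spec)[-1] == "k"


class TestPhotoperiodResponse:
    def test_at_threshold(self):
        assert photoperiod_response(12.0, 12.0, "ratio") == pytest.approx(1.0)
        assert photoperiod_response(12.0, 12.0, "one_minus_ratio") == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert photoperiod_response(8.0, 12.0, "ratio") == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_clamped_below_zero(self):
        assert photoperiod_response(20.0, 10.0, "one_minus_ratio") == 0.0

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            photoperiod_response(10.0, 0.0)


class TestSpringSummerMean:
    def test_constant_series(self):
        assert spring_summer_mean_temp(np.full(365, 15.0), {3, 4, 5}) == pytest.approx(15.0)

    def test_june_slice_oracle(self):
        doy = np.arange(1, 366)
        temp = 10.0 + 12.0 * np.cos(2 * np.pi * (doy - 200) / 365)
        expected = temp[151:181].mean()  # days 152..181 are June
        assert spring_summer_mean_temp(temp, {6}) == pytest.approx(expected, abs=1e-12)

    def test_all_months_is_annual_mean(self):
        rng = np.random.default_rng(3)
        temp = rng.normal(10, 5, 365)
        assert spring_summer_mean_temp(temp, set(range(1, 13))) == pytest.approx(temp.mean())

    def test_empty_months(self):
        with pytest.raises(ValueError):
            spring_summer_mean_temp(np.zeros(365), set())


class TestLudAnomaly:
    def test_centering(self):
        assert lud_anomaly([100, 110, 120]).tolist() == [-10.0, 0.0, 10.0]

    def test_constant(self):
        assert np.all(lud_anomaly([105, 105, 105, 105]) == 0.0)

    def test_sums_to_zero(self):
        rng = np.random.default_rng(8)
        a = lud_anomaly(rng.uniform(90, 130, 25))
        assert abs(a.sum()) < 1e-9

    def test_nan_passthrough(self):
        a = lud_anomaly([100.0, np.nan, 120.0])
        assert np.isnan(a[1]) and a[0] == -10.0

    def test_too_few(self):
        with pytest.raises(ValueError):
            lud_anomaly([100.0, np.nan])


class TestCddModel:
    def test_hand_trace(self):
        # post-solstice temps [25, 18, 15, 22, 10]: onset on the 18C day,
        # increments 2, 5, 0, 10 -> cumulative 2, 7, 7, 17; threshold 10
        # crossed on the 10C day
        spec = SenescenceModelSpec("CDD")
        params = ModelParams(spec, {"t_th": 20.0, "cdd_th": 10.0})
        temp = synthetic_temp_year([25.0, 18.0, 15.0, 22.0, 10.0], fill=30.0)
        # keep everything after warm so no later accumulation confusion
        trace = predict_dfs(spec, params, temp, latitude=45.0)
        assert trace.onset_day == 173
        assert trace.crossing_day == 176
        state = trace.daily_state
        assert state[172] == pytest.approx(2.0)
        assert state[173] == pytest.approx(7.0)
        assert state[174] == pytest.approx(7.0)
        assert state[175] == pytest.approx(17.0)

    def test_no_onset_is_missing(self):
        spec = SenescenceModelSpec("CDD")
        params = ModelParams(spec, {"t_th": 5.0, "cdd_th": 10.0})
        trace = predict_dfs(spec, params, np.full(365, 20.0), latitude=45.0)
        assert trace.onset_day is None and trace.crossing_day is None

    def test_threshold_never_reached(self):
        spec = SenescenceModelSpec("CDD")
        params = ModelParams(spec, {"t_th": 20.0, "cdd_th": 900.0})
        temp = synthetic_temp_year([19.0] * 10, fill=30.0)
        trace = predict_dfs(spec, params, temp, latitude=45.0)
        assert trace.onset_day == 172
        assert trace.crossing_day is None
        assert trace.valid

    def test_raising_threshold_temp_never_delays(self, site):
        # weak monotonicity: larger t_th -> accumulation starts earlier and
        # grows faster -> DFS no later
        spec = SenescenceModelSpec("CDD")
        temp = site.daily_temp[2005]
        previous = None
        for t_th in np.linspace(10, 30, 9):
            params = ModelParams(spec, {"t_th": float(t_th), "cdd_th": 80.0})
            trace = predict_dfs(spec, params, temp, site.latitude)
            day = trace.crossing_day if trace.crossing_day is not None else 10**6
            if previous is not None:
                assert day <= previous
            previous = day


class TestDmFamily:
    def test_unit_rate_limit(self):
        # x = y = 0 -> rate 1 on qualifying days; DFS = onset + ceil(Y) - 1
        spec = SenescenceModelSpec("DM", photoperiod_variant="ratio")
        params = ModelParams(spec, {"t_b": 10.0, "p_s": 24.0, "x": 0.0, "y": 0.0, "y_crit": 7.0})
        temp = synthetic_temp_year([5.0] * 194, fill=30.0)
        trace = predict_dfs(spec, params, temp, latitude=45.0)
        assert trace.onset_day == 172
        assert trace.crossing_day == 172 + 7 - 1

    def test_conjunctive_onset(self):
        # temperature qualifies from the solstice, but the photoperiod at
        # 50N only shortens to 13h later in the season -> onset is delayed
        spec = SenescenceModelSpec("DM")
        params = ModelParams(spec, {"t_b": 20.0, "p_s": 13.0, "x": 1.0, "y": 1.0, "y_crit": 30.0})
        temp = np.full(365, 10.0)
        trace = predict_dfs(spec, params, temp, latitude=50.0)
        photo = np.asarray(day_length(50.0, np.arange(1, 366)))
        first_ok = int(np.nonzero((photo <= 13.0) & (np.arange(1, 366) >= 172))[0][0]) + 1
        assert trace.onset_day == first_ok

    def test_warm_days_contribute_zero(self):
        spec = SenescenceModelSpec("DM")
        params = ModelParams(spec, {"t_b": 15.0, "p_s": 24.0, "x": 1.0, "y": 0.0, "y_crit": 50.0})
        temp = synthetic_temp_year([10.0, 25.0, 10.0, 25.0] * 10, fill=30.0)
        trace = predict_dfs(spec, params, temp, latitude=45.0)
        inc = trace.daily_increment
        # increments on warm days after onset are exactly zero
        warm = (temp > 15.0) & (np.arange(1, 366) >= trace.onset_day)
        assert np.all(inc[warm] == 0.0)

    def test_state_non_decreasing(self, site):
        spec = SenescenceModelSpec("DM")
        params = ModelParams(spec, {"t_b": 18.0, "p_s": 15.0, "x": 1.3, "y": 0.7, "y_crit": 40.0})
        for year in (2001, 2010, 2020):
            trace = predict_dfs(spec, params, site.daily_temp[year], site.latitude)
            assert np.all(np.diff(trace.daily_state) >= 0)

    def test_trace_replay(self, site):
        spec = SenescenceModelSpec("DM")
        params = ModelParams(spec, {"t_b": 18.0, "p_s": 15.0, "x": 1.0, "y": 1.0, "y_crit": 30.0})
        trace = predict_dfs(spec, params, site.daily_temp[2003], site.latitude)
        assert trace.crossing_day is not None
        replay = np.cumsum(trace.daily_increment)
        crossing = int(np.nonzero(replay >= trace.threshold)[0][0]) + 1
        assert crossing == trace.crossing_day


class TestSiamDmt:
    def test_siam_threshold_from_lud(self, site):
        spec = SenescenceModelSpec("SIAM")
        params = ModelParams(spec, {"t_b": 18.0, "p_s": 15.0, "x": 1.0, "y": 1.0,
                                    "a": 40.0, "b": 2.0})
        trace = predict_dfs(spec, params, site.daily_temp[2001], site.latitude,
                            lud_anomaly_value=3.0)
        assert trace.threshold == pytest.approx(40.0 + 2.0 * 3.0)

    def test_siam_requires_lud(self, site):
        spec = SenescenceModelSpec("SIAM")
        params = ModelParams(spec, {"t_b": 18.0, "p_s": 15.0, "x": 1.0, "y": 1.0,
                                    "a": 40.0, "b": 2.0})
        with pytest.raises(ValueError, match="SIAM"):
            predict_dfs(spec, params, site.daily_temp[2001], site.latitude)

    def test_nonpositive_threshold_invalid_year(self, site):
        spec = SenescenceModelSpec("SIAM")
        params = ModelParams(spec, {"t_b": 18.0, "p_s": 15.0, "x": 1.0, "y": 1.0,
                                    "a": 10.0, "b": 20.0})
        trace = predict_dfs(spec, params, site.daily_temp[2001], site.latitude,
                            lud_anomaly_value=-5.0)
        assert not trace.valid
        assert trace.crossing_day is None

    def test_dmt_computes_tss_from_temps(self, site):
        spec = SenescenceModelSpec("DMT")
        params = ModelParams(spec, {"t_b": 18.0, "p_s": 15.0, "x": 1.0, "y": 1.0,
                                    "a": 20.0, "b": 1.0})
        temp = site.daily_temp[2001]
        trace = predict_dfs(spec, params, temp, site.latitude)
        tss = spring_summer_mean_temp(temp, spec.tss_months)
        assert trace.threshold == pytest.approx(20.0 + tss)


class TestAlanVariants:
    @pytest.fixture()
    def alan_series(self, site):
        return site.alan

    @pytest.mark.parametrize("family", ["CDD", "DM", "SIAM", "DMT"])
    def test_k_zero_identical_to_base(self, family, site, alan_series):
        base_spec = SenescenceModelSpec(family)
        alan_spec = SenescenceModelSpec(family, alan_enabled=True)
        base_vals = {
            "CDD": {"t_th": 22.0, "cdd_th": 120.0},
            "DM": {"t_b": 20.0, "p_s": 15.0, "x": 1.0, "y": 1.0, "y_crit": 50.0},
            "SIAM": {"t_b": 20.0, "p_s": 15.0, "x": 1.0, "y": 1.0, "a": 50.0, "b": 1.0},
            "DMT": {"t_b": 20.0, "p_s": 15.0, "x": 1.0, "y": 1.0, "a": 30.0, "b": 1.0},
        }[family]
        bp = ModelParams(base_spec, base_vals)
        ap = ModelParams(alan_spec, {**base_vals, "k": 0.0})
        for year in site.years.tolist():
            tb = predict_dfs(base_spec, bp, site.daily_temp[year], site.latitude,
                             lud_anomaly_value=0.0)
            ta = predict_dfs(alan_spec, ap, site.daily_temp[year], site.latitude,
                             year=year, alan=alan_series, lud_anomaly_value=0.0)
            assert ta.crossing_day == tb.crossing_day
            assert np.array_equal(ta.daily_state, tb.daily_state)

    def test_sign_consistency(self, site, alan_series):
        # with alan_i < alan_max the exponent k*(alan_i - alan_max)/alan_max
        # is positive for k < 0 (ALANin > 1, faster accumulation, DFS no
        # later) and negative for k > 0 (ALANin < 1, DFS no earlier)
        spec_b = SenescenceModelSpec("DM")
        spec_a = SenescenceModelSpec("DM", alan_enabled=True)
        vals = {"t_b": 20.0, "p_s": 15.0, "x": 1.0, "y": 1.0, "y_crit": 50.0}
        bp = ModelParams(spec_b, vals)
        for k, cmp in [(-3.0, np.less_equal), (3.0, np.greater_equal)]:
            ap = ModelParams(spec_a, {**vals, "k": k})
            for year in site.years[:-1].tolist():  # last year may be the max itself
                tb = predict_dfs(spec_b, bp, site.daily_temp[year], site.latitude)
                ta = predict_dfs(spec_a, ap, site.daily_temp[year], site.latitude,
                                 year=year, alan=alan_series)
                if tb.crossing_day is not None and ta.crossing_day is not None:
                    assert cmp(ta.crossing_day, tb.crossing_day)

    def test_alan_required(self, site):
        spec = SenescenceModelSpec("CDD", alan_enabled=True)
        params = ModelParams(spec, {"t_th": 22.0, "cdd_th": 120.0, "k": 1.0})
        with pytest.raises(ValueError, match="ALAN"):
            predict_dfs(spec, params, site.daily_temp[2001], site.latitude)


class TestBounds:
    def test_default_bounds_sane(self):
        assert DEFAULT_BOUNDS["t_th"] == (0.0, 50.0)
        assert DEFAULT_BOUNDS["x"] == (0.0, 2.0)
        assert DEFAULT_BOUNDS["y"] == (0.0, 2.0)
        assert DEFAULT_BOUNDS["k"] == (-10.0, 10.0)
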