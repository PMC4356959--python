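import numpy as np
import pytest
from scipy import stats as sps

from otochron.envcorr import (
    annual_mean,
    correlation_table,
    lagged_correlations,
    linear_detrend,
    pearson_p,
    seasonal_means,
)
from otochron.io import Chronology, EnvSeries, MonthlyEnvSeries, ValidationError


def _monthly(values_by_year_month, name="sst"):
    ys, ms, vs = zip(*[(y, m, v) for (y, m), v in values_by_year_month.items()])
    return MonthlyEnvSeries(name=name, years=np.array(ys), months=np.array(ms),
                            values=np.array(vs))


def _full_monthly(years, fill=1.0):
    return _monthly({(y, m): fill for y in years for m in range(1, 13)})


class TestSeasonalMeans:
    def test_constant_series_preserved(self):
        env = seasonal_means(_full_monthly(range(1990, 1995), 3.5), "JJA")
        np.testing.assert_allclose(env.values, 3.5)

    def test_djf_uses_previous_december(self):
        data = {(y, m): 0.0 for y in (1999, 2000) for m in range(1, 13)}
        data[(1999, 12)] = 0.0
        data[(2000, 1)] = 3.0
        data[(2000, 2)] = 3.0
        env = seasonal_means(_monthly(data), "DJF")
        assert env.value_for([2000])[0] == pytest.approx(2.0)

    def test_incomplete_season_omitted(self):
        data = {(y, m): 1.0 for y in (1999, 2000, 2001) for m in range(1, 13)}
        del data[(2000, 1)]
        env = seasonal_means(_monthly(data), "DJF")
        assert 2000 not in env.years.tolist()  # missing Jan 2000
        assert 1999 not in env.years.tolist()  # needs Dec 1998
        assert 2001 in env.years.tolist()

    def test_annual_mean_requires_all_twelve_months(self):
        data = {(2000, m): float(m) for m in range(1, 13)}
        env = annual_mean(_monthly(data))
        assert env.value_for([2000])[0] == pytest.approx(6.5)
        del data[(2000, 7)]
        with pytest.raises(ValidationError):
            annual_mean(_monthly(data))

    def test_unknown_season_rejected(self):
        with pytest.raises(ValidationError):
            seasonal_means(_full_monthly(range(1990, 1993)), "XYZ")


class TestLinearDetrend:
    def test_exact_line_gives_zero_residuals(self):
        years = np.arange(1980, 2000)
        env = EnvSeries("sl", years, 3.0 + 0.01 * (years - 1980))
        out = linear_detrend(env)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)
        assert "linear_detrended" in out.preprocessing

    def test_known_residuals_recovered(self):
        rng = np.random.default_rng(0)
        years = np.arange(1980, 2010)
        e = rng.normal(0, 0.05, len(years))
        e -= np.polyval(np.polyfit(years.astype(float), e, 1),
                        years.astype(float))  # residual part of the noise
        env = EnvSeries("sl", years, 2.0 + 0.03 * years + e)
        out = linear_detrend(env)
        np.testing.assert_allclose(out.values, e, atol=1e-9)

    def test_residuals_orthogonal_to_year(self):
        rng = np.random.default_rng(1)
        years = np.arange(1980, 2010)
        env = EnvSeries("sl", years, rng.normal(size=len(years)))
        out = linear_detrend(env)
        assert abs(out.values.mean()) < 1e-9
        assert abs(np.corrcoef(out.values, years)[0, 1]) < 1e-9


class TestPearsonP:
    @pytest.mark.parametrize("r,n,expected", [
        (0.61, 15, 0.016),
        (-0.62, 15, 0.014),
    ])
    def test_reported_significance_reproduced(self, r, n, expected):
        assert round(pearson_p(r, n), 3) == expected

    def test_zero_correlation_uninformative(self):
        for n in (3, 15, 100):
            assert pearson_p(0.0, n) == pytest.approx(1.0)

    def test_sign_symmetric(self):
        for r in (0.1, 0.5, 0.9):
            assert pearson_p(r, 20) == pearson_p(-r, 20)

    def test_monotone_in_effect_and_sample_size(self):
        rs = np.linspace(0.05, 0.95, 10)
        ps = [pearson_p(r, 15) for r in rs]
        assert np.all(np.diff(ps) < 0)
        ns = [5, 10, 20, 50, 200]
        ps = [pearson_p(0.3, n) for n in ns]
        assert np.all(np.diff(ps) < 0)

    def test_perfect_correlation(self):
        assert pearson_p(1.0, 10) == 0.0

    def test_agrees_with_scipy_exact_test(self):
        rng = np.random.default_rng(2)
        for n in (8, 15, 40):
            x, y = rng.standard_normal((2, n))
            r, p_ref = sps.pearsonr(x, y)
            assert pearson_p(float(r), n) == pytest.approx(p_ref, rel=1e-9)


class TestLaggedCorrelations:
    def _chron(self, values, first_year=1988):
        return Chronology(first_year, values, np.full(len(values), 10))

    def test_env_equal_to_chronology(self):
        rng = np.random.default_rng(3)
        vals = 1 + 0.1 * rng.standard_normal(20)
        chron = self._chron(vals)
        env = EnvSeries("self", chron.years, vals)
        res = {c.lag: c for c in
               lagged_correlations(chron, (1990, 2004), [env])}
        assert res["current"].r == pytest.approx(1.0)
        assert res["current"].p == 0.0
        # previous-year r equals the windowed lag-1 autocorrelation
        w = chron.window(1990, 2004)
        w_prev = chron.window(1989, 2003)
        assert res["previous"].r == pytest.approx(
            np.corrcoef(w, w_prev)[0, 1])

    def test_sample_size_equals_window_length(self):
        rng = np.random.default_rng(4)
        chron = self._chron(1 + 0.1 * rng.standard_normal(20))
        env = EnvSeries("e", np.arange(1985, 2010),
                        rng.standard_normal(25))
        for c in lagged_correlations(chron, (1990, 2004), [env]):
            assert c.n == 15

    def test_sparse_variable_omitted_with_warning(self):
        rng = np.random.default_rng(5)
        chron = self._chron(1 + 0.1 * rng.standard_normal(20))
        env = EnvSeries("sparse", np.array([1990, 1992]),
                        np.array([1.0, 2.0]))
        with pytest.warns(UserWarning, match="sparse"):
            res = lagged_correlations(chron, (1990, 2004), [env])
        assert res == []

    def test_table_shape_and_stars(self):
        rng = np.random.default_rng(6)
        vals = 1 + 0.1 * rng.standard_normal(20)
        chron = self._chron(vals)
        envs = [EnvSeries("self", chron.years, vals),
                EnvSeries("noise", chron.years,
                          rng.standard_normal(20))]
        table = correlation_table(
            lagged_correlations(chron, (1990, 2004), envs))
        assert list(table["variable"]) == ["self", "noise"]
        assert table.loc[0, "current_sig"] == "*"


def test_null_rejection_rate_is_nominal():
    """Independent chronology/environment pairs (n = 15) reject at p < 0.05
    about 5% of the time."""
    rng = np.random.default_rng(123)
    n_sim = 10_000
    x = rng.standard_normal((n_sim, 15))
    y = rng.standard_normal((n_sim, 15))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    p = np.array([pearson_p(float(ri), 15) for ri in r])
    assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)
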