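import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_index_set
from otochron.chronology import (
    ChronStats,
    ar_standardize,
    eps,
    mean_chronology,
    mean_sensitivity,
    rbar_windowed,
    select_window,
    tukey_biweight_mean,
)
from otochron.io import IndexSeries, ValidationError


def _series(indices, owner="F1", first_year=1980):
    return IndexSeries(owner_id=owner, level="ims", first_year=first_year,
                       indices=np.asarray(indices, dtype=float))


class TestMeanChronology:
    def test_identical_series_reproduced_with_full_depth(self):
        idx = np.exp(np.random.default_rng(0).normal(0, 0.1, 20))
        chron = mean_chronology([_series(idx, f"F{i}") for i in range(44)])
        np.testing.assert_allclose(chron.values, idx)
        assert np.all(chron.sample_depth == 44)

    def test_arithmetic_mean_and_depth(self):
        chron = mean_chronology([_series([1.0, 1.2]), _series([1.2, 0.8], "F2")])
        np.testing.assert_allclose(chron.values, [1.1, 1.0])
        np.testing.assert_array_equal(chron.sample_depth, [2, 2])

    def test_biweight_downweights_outlier(self):
        x = np.r_[np.ones(29), 5.0]
        assert abs(tukey_biweight_mean(x) - 1.0) < abs(x.mean() - 1.0)

    def test_robust_variant_resists_outlier_series(self):
        series = [_series(np.ones(10) * (5.0 if i == 0 else 1.0), f"F{i}")
                  for i in range(30)]
        robust = mean_chronology(series, robust=True)
        plain = mean_chronology(series)
        assert np.all(np.abs(robust.values - 1) < np.abs(plain.values - 1))

    def test_mean_near_one_on_simulated_indices(self, weak_dataset):
        from otochron.detrend import detrend_dataset

        ims, _ = detrend_dataset(weak_dataset.records, 9.0)
        chron = mean_chronology(ims)
        covered = chron.sample_depth >= 10
        assert abs(chron.values[covered].mean() - 1.0) < 0.1


class TestMeanSensitivity:
    def test_constant_series_is_zero(self):
        assert mean_sensitivity(np.ones(10)) == 0.0

    @pytest.mark.parametrize("series,expected", [
        ([1, 3, 1, 3], 1.0),   # each term 2*2/4
        ([1, 1, 3], 0.5),      # terms 0 and 1
    ])
    def test_hand_computed_values(self, series, expected):
        assert mean_sensitivity(series) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 9999))
    def test_scale_invariant(self, scale, seed):
        x = np.exp(np.random.default_rng(seed).normal(0, 0.2, 15))
        assert mean_sensitivity(scale * x) == pytest.approx(
            mean_sensitivity(x), rel=1e-12)

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValidationError):
            mean_sensitivity([1.0, 0.0, 2.0])


class TestEps:
    def test_single_series_identity(self):
        for r in (-0.2, 0.0, 0.3, 0.9):
            assert eps(r, 1) == pytest.approx(r)

    def test_hand_computed(self):
        assert eps(0.25, 12) == pytest.approx(0.8)  # 3 / 3.75

    def test_perfect_agreement_saturates(self):
        for n in (1, 2, 10, 44):
            assert eps(1.0, n) == pytest.approx(1.0)

    def test_monotone_in_n_and_rbar(self):
        grid_r = np.linspace(0.01, 0.9, 12)
        grid_n = np.arange(2, 60, 7)
        for n in grid_n:
            vals = [eps(r, n) for r in grid_r]
            assert np.all(np.diff(vals) > 0)
        for r in grid_r:
            vals = [eps(r, n) for n in grid_n]
            assert np.all(np.diff(vals) > 0)

    def test_degenerate_denominator_guarded(self):
        with pytest.raises(ValidationError):
            eps(-0.5, 44)


class TestRbarWindowed:
    def test_identical_series_have_unit_rbar_zero_se(self):
        idx = np.exp(np.random.default_rng(1).normal(0, 0.1, 25))
        stats = rbar_windowed([_series(idx, f"F{i}") for i in range(3)], 15)
        assert stats
        for s in stats:
            assert s.rbar == pytest.approx(1.0, abs=1e-9)
            assert s.rbar_se == pytest.approx(0.0, abs=1e-9)

    def test_two_series_single_pair(self):
        rng = np.random.default_rng(2)
        a, b = (np.exp(rng.normal(0, 0.1, 20)) for _ in range(2))
        stats = rbar_windowed([_series(a), _series(b, "F2")], 15)
        s = stats[0]
        assert s.n_pairs == 1 and s.rbar_se == 0.0
        expected = np.corrcoef(a[:15], b[:15])[0, 1]
        assert s.rbar == pytest.approx(expected)

    def test_windows_without_two_covering_series_absent(self):
        a = _series(np.exp(np.random.default_rng(3).normal(0, 0.1, 40)),
                    "F1", 1960)
        b = _series(np.exp(np.random.default_rng(4).normal(0, 0.1, 40)),
                    "F2", 1990)
        stats = rbar_windowed([a, b], 15)
        assert all(s.window_start >= 1990 for s in stats)

    def test_rbar_tracks_common_variance_share(self):
        """With a white common signal (no detrending loss) windowed rbar is
        an unbiased estimate of the variance share."""
        rng = np.random.default_rng(5)
        share = 0.3
        vals = []
        for _ in range(30):
            stats = rbar_windowed(make_index_set(rng, n=30, years=20,
                                                 share=share), 15)
            vals += [s.rbar for s in stats]
        assert np.mean(vals) == pytest.approx(share, abs=0.03)


class TestSelectWindow:
    def _stats(self, start, rbar, se, n_pairs=100):
        return ChronStats(window_start=start, window_end=start + 14,
                          rbar=rbar, rbar_se=se, n_pairs=n_pairs,
                          sample_depth=20, eps=eps(rbar, 20),
                          mean_sensitivity=0.1)

    def test_two_sigma_criterion(self):
        stats = [self._stats(1989, 0.03, 0.02),
                 self._stats(1990, 0.035, 0.012),
                 self._stats(1991, 0.04, 0.021)]
        chosen = select_window(stats)
        assert chosen.window_start == 1990  # only 0.035 - 0.024 > 0

    def test_most_pairs_wins_among_qualifiers(self):
        stats = [self._stats(1989, 0.2, 0.01, 100),
                 self._stats(1990, 0.2, 0.01, 120),
                 self._stats(1991, 0.2, 0.01, 110)]
        assert select_window(stats).n_pairs == 120

    def test_tie_broken_by_earliest_start(self):
        stats = [self._stats(1991, 0.2, 0.01, 100),
                 self._stats(1989, 0.2, 0.01, 100)]
        assert select_window(stats).window_start == 1989

    def test_no_adequate_signal_returns_none(self):
        stats = [self._stats(1989, 0.01, 0.02)]
        assert select_window(stats) is None


class TestArStandardize:
    def test_white_noise_mostly_selects_order_zero(self):
        """Under the null AIC accepts a spurious AR term with probability
        ~P(chi2_1 > 2) = 0.16 per candidate order, so order 0 is selected
        for roughly 70% of white-noise series (length 30)."""
        rng = np.random.default_rng(6)
        series = [_series(np.exp(rng.normal(0, 0.1, 30)), f"F{i}")
                  for i in range(200)]
        res = ar_standardize(series, max_order=3)
        assert 0.60 <= (res.orders["order"] == 0).mean() <= 0.85

    def test_ar1_parameter_recovery(self):
        rng = np.random.default_rng(7)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            x = np.zeros(200)
            for t in range(1, 200):
                x[t] = 0.7 * x[t - 1] + rng.standard_normal()
            s = _series(np.exp(0.05 * (x - x.mean()) / x.std()), "F1")
            res = ar_standardize([s], max_order=3)
            order = int(res.orders["order"].iloc[0])
            if order >= 1:
                phi = res.orders["coefs"].iloc[0][0]
                ok += 0.55 <= phi <= 0.85
        assert ok / n_rep >= 0.90

    def test_residual_chronology_is_whitened(self):
        rng = np.random.default_rng(8)
        series = []
        for i in range(20):
            x = np.zeros(60)
            for t in range(1, 60):
                x[t] = 0.6 * x[t - 1] + rng.standard_normal()
            series.append(_series(np.exp(0.1 * (x - x.mean()) / x.std()),
                                  f"F{i}"))
        res = ar_standardize(series, max_order=3)
        v = res.residual.values
        v = v[np.isfinite(v)]
        rho1 = np.corrcoef(v[1:], v[:-1])[0, 1]
        assert abs(rho1) < 0.15

    def test_variants_labelled(self, weak_dataset):
        from otochron.detrend import detrend_dataset

        ims, _ = detrend_dataset(weak_dataset.records, 9.0)
        res = ar_standardize(ims)
        assert res.residual.variant == "residual"
        assert res.ar_standardized.variant == "ar_standardized"
        assert len(res.orders) == len(ims)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            ar_standardize([_series(np.ones(6))], max_order=3)
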