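import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import Table2x2

import lbpclaims as L
from oracles import wilson_by_bisection


class TestWilsonInterval:
    def test_zero_successes_lower_bound_is_zero(self):
        for n in (1, 10, 1000):
            lo, hi = L.wilson_interval(0, n, 0.99)
            assert lo == 0.0 and 0 < hi < 1

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = L.wilson_interval(50, 50, 0.95)
        assert hi == 1.0 and 0 < lo < 1

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 100_000),
        frac=st.floats(0, 1),
        confidence=st.sampled_from([0.8, 0.9, 0.95, 0.99]),
    )
    def test_complement_symmetry(self, n, frac, confidence):
        k = int(round(frac * n))
        lo, hi = L.wilson_interval(k, n, confidence)
        lo_c, hi_c = L.wilson_interval(n - k, n, confidence)
        assert lo == pytest.approx(1 - hi_c, abs=1e-12)
        assert hi == pytest.approx(1 - lo_c, abs=1e-12)

    def test_matches_score_test_inversion_oracle(self):
        for n in (10, 137, 10_000, 100_000):
            for k in {0, 1, n // 7, n // 2, n - 1, n}:
                for conf in (0.9, 0.95, 0.99):
                    lo, hi = L.wilson_interval(k, n, conf)
                    olo, ohi = wilson_by_bisection(k, n, conf)
                    assert abs(lo - olo) < 1e-10
                    assert abs(hi - ohi) < 1e-10

    def test_width_shrinks_with_n_at_fixed_phat(self):
        widths = []
        for n in (100, 1_000, 10_000, 100_000):
            lo, hi = L.wilson_interval(int(0.015 * n), n, 0.99)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            L.wilson_interval(1, 0, 0.99)
        with pytest.raises(ValueError):
            L.wilson_interval(5, 3, 0.99)
        with pytest.raises(ValueError):
            L.wilson_interval(1, 10, 1.5)


class TestPrevalence:
    def make_inputs(self, cases, denom):
        counts = pd.DataFrame(
            {"year": 2000, "sex": "male", "age_band": "18-34", "cases": [cases]}
        )
        denoms = pd.DataFrame(
            {"year": 2000, "sex": "male", "age_band": "18-34", "count": [denom]}
        )
        return counts, denoms

    def test_zero_cases(self):
        prev = L.prevalence(*self.make_inputs(0, 1000))
        row = prev.iloc[0]
        assert row.point == 0.0 and row.lower == 0.0 and row.upper > 0

    def test_all_cases(self):
        row = L.prevalence(*self.make_inputs(1000, 1000)).iloc[0]
        assert row.point == 100.0 and row.upper == 100.0

    def test_point_is_percent_ratio(self):
        row = L.prevalence(*self.make_inputs(150, 10_000), 0.99).iloc[0]
        assert row.point == pytest.approx(1.5)
        lo, hi = L.wilson_interval(150, 10_000, 0.99)
        assert row.lower == pytest.approx(100 * lo)
        assert row.upper == pytest.approx(100 * hi)

    def test_missing_denominator_names_stratum(self):
        counts, denoms = self.make_inputs(5, 100)
        counts.loc[0, "age_band"] = "35-49"
        with pytest.raises(ValueError, match="35-49"):
            L.prevalence(counts, denoms)

    def test_zero_denominator_emits_explicit_missing_row(self):
        counts, denoms = self.make_inputs(0, 0)
        prev = L.prevalence(counts, denoms)
        assert len(prev) == 1 and np.isnan(prev.iloc[0].point)

    def test_denominator_only_stratum_counts_zero_cases(self):
        counts, denoms = self.make_inputs(5, 100)
        denoms = pd.concat(
            [denoms, pd.DataFrame({"year": [2000], "sex": ["female"],
                                   "age_band": ["18-34"], "count": [50]})]
        )
        prev = L.prevalence(counts, denoms).set_index("sex")
        assert prev.loc["female", "cases"] == 0
        assert prev.loc["female", "point"] == 0.0


class TestRelativeRisk:
    def test_printed_prevalence_pair_gives_printed_rr(self):
        # 35-49 in 2000: male 2.05%, female 1.65% on equal denominators
        rr = L.relative_risk(20500, 1_000_000, 16500, 1_000_000)
        assert round(rr.rr, 2) == 1.24

    def test_identical_groups(self):
        rr = L.relative_risk(120, 1000, 120, 1000, 0.99)
        assert rr.rr == pytest.approx(1.0)
        assert rr.lower < 1 < rr.upper

    def test_reciprocity(self):
        a = L.relative_risk(30, 500, 50, 700, 0.99)
        b = L.relative_risk(50, 700, 30, 500, 0.99)
        assert a.rr * b.rr == pytest.approx(1.0, abs=1e-12)
        assert a.lower == pytest.approx(1 / b.upper, rel=1e-12)
        assert a.upper == pytest.approx(1 / b.lower, rel=1e-12)

    def test_matches_log_method_of_statsmodels(self):
        k1, n1, k0, n0 = 150, 10_000, 95, 9_000
        mine = L.relative_risk(k1, n1, k0, n0, 0.99)
        t = Table2x2([[k1, n1 - k1], [k0, n0 - k0]])
        lo, hi = t.riskratio_confint(alpha=0.01)
        assert mine.rr == pytest.approx(t.riskratio, rel=1e-12)
        assert mine.lower == pytest.approx(lo, rel=1e-9)
        assert mine.upper == pytest.approx(hi, rel=1e-9)

    def test_zero_events_are_an_error(self):
        with pytest.raises(ValueError):
            L.relative_risk(0, 100, 5, 100)
        with pytest.raises(ValueError):
            L.relative_risk(5, 100, 0, 100)


class TestTrendAndVariation:
    def test_percent_variation_examples(self):
        assert round(L.percent_variation(1.13, 0.70)) == -38
        assert round(L.percent_variation(1.58, 1.83)) == 16
        assert L.percent_variation(2.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            L.percent_variation(0.0, 1.0)

    def test_constant_series_slope_zero(self):
        assert L.trend_slope([(y, 1.5) for y in range(2000, 2008)]) == pytest.approx(0.0)

    def test_exact_linear_series(self):
        pts = [(y, 1.0 - 0.05 * (y - 2000)) for y in range(2000, 2008)]
        assert L.trend_slope(pts) == pytest.approx(-0.05, abs=1e-12)

    def test_noisy_series_matches_closed_form(self):
        rng = np.random.default_rng(7)
        years = np.arange(2000, 2008)
        vals = 1.6 - 0.04 * (years - 2000) + rng.normal(0, 0.05, 8)
        expected = ((years - years.mean()) * (vals - vals.mean())).sum() / (
            (years - years.mean()) ** 2
        ).sum()
        assert L.trend_slope(list(zip(years, vals))) == pytest.approx(expected, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            L.trend_slope([(2000, 1.0)])
        with pytest.raises(ValueError):
            L.trend_slope([(2000, 1.0), (2000, 2.0)])


class TestWilsonCoverage:
    def test_99pct_interval_covers_true_p_between_98_and_100(self):
        """Empirical coverage of the 99% interval at p=0.015, n=1e5."""
        rng = np.random.default_rng(20240601)
        p, n, draws = 0.015, 100_000, 2_000
        k = rng.binomial(n, p, draws)
        lo, hi = L.wilson_interval(k, np.full(draws, n), 0.99)
        coverage = np.mean((lo <= p) & (p <= hi))
        assert 0.98 <= coverage <= 1.0


class TestReportTables:
    def make_counts(self, spec):
        rows = [
            {"year": y, "sex": s, "age_band": b, "cases": k}
            for (y, s, b), k in spec.items()
        ]
        return pd.DataFrame(rows)

    def make_denoms(self, spec, n):
        rows = [
            {"year": y, "sex": s, "age_band": b, "count": n}
            for (y, s, b) in spec
        ]
        return pd.DataFrame(rows)

    def test_two_identical_years_zero_variation(self, cfg, tmp_path):
        spec = {}
        for year in (2000, 2007):
            for sex in ("male", "female"):
                spec[(year, sex, "18-34")] = 120
        counts = self.make_counts(spec)
        denoms = self.make_denoms(spec, 10_000)
        tables = L.report_tables(counts, denoms, cfg, out_dir=tmp_path)
        t1 = tables["prevalence"]
        assert (t1["pct_var"] == 0).all()
        assert (tmp_path / "table_prevalence.csv").exists()
        t2 = tables["relative_risk"]
        assert (t2["rr"] == 1.0).all()

    def test_empty_case_set_gives_zero_prevalence_and_empty_rr(self, cfg):
        spec = {(2000, "male", "18-34"): 0, (2007, "male", "18-34"): 0}
        counts = self.make_counts(spec)
        denoms = self.make_denoms(spec, 5_000)
        tables = L.report_tables(counts, denoms, cfg)
        assert (tables["prevalence"][["prev_2000", "prev_2007"]] == 0).all().all()
        assert tables["relative_risk"]["rr"].isna().all() or tables["relative_risk"].empty

    def test_aggregate_prevalence_pools_before_division(self):
        counts = pd.DataFrame(
            {
                "year": [2000, 2000],
                "sex": ["male", "male"],
                "age_band": ["18-34", "35-49"],
                "cases": [10, 90],
            }
        )
        denoms = pd.DataFrame(
            {
                "year": [2000, 2000],
                "sex": ["male", "male"],
                "age_band": ["18-34", "35-49"],
                "count": [10_000, 1_000],
            }
        )
        agg = L.aggregate_prevalence(counts, denoms)
        # pooled: 100/11000 = 0.909% — NOT the 4.55% average of band rates
        assert agg.iloc[0].point == pytest.approx(100 * 100 / 11_000)
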