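import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beemon import community_metrics as cm
from beemon.core_io import SiteGrouping, build_month_matrix, build_year_matrix


class TestInverseSimpson:
    def test_equal_abundances(self):
        assert cm.inverse_simpson([5, 5, 5, 5]) == pytest.approx(4.0)

    def test_monoculture(self):
        assert cm.inverse_simpson([7]) == pytest.approx(1.0)

    def test_formula_oracle(self):
        # D = 1 / (0.1^2 + 0.1^2 + 0.8^2) = 1/0.66
        assert cm.inverse_simpson([10, 10, 80]) == pytest.approx(1 / 0.66)

    def test_all_zero_is_nan(self):
        assert np.isnan(cm.inverse_simpson([0, 0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cm.inverse_simpson([3, -1])

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                        max_size=8).filter(lambda c: sum(c) > 0),
        scale=st.integers(min_value=1, max_value=9),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_and_padding_invariance(self, counts, scale):
        d = cm.inverse_simpson(counts)
        assert cm.inverse_simpson([c * scale for c in counts]) == pytest.approx(d)
        assert cm.inverse_simpson(counts + [0, 0]) == pytest.approx(d)
        s = sum(1 for c in counts if c > 0)
        assert 1.0 - 1e-9 <= d <= s + 1e-9


class TestEvenness:
    def test_equal_abundances(self):
        assert cm.evenness([5, 5, 5, 5]) == pytest.approx(1.0)

    def test_monoculture(self):
        assert cm.evenness([7]) == pytest.approx(1.0)

    def test_derived_from_inverse_simpson(self):
        assert cm.evenness([10, 10, 80]) == pytest.approx((1 / 0.66) / 3)

    def test_pielou_option(self):
        p = np.array([0.5, 0.5])
        expected = -(p * np.log(p)).sum() / np.log(2)
        assert cm.evenness([5, 5], method="pielou") == pytest.approx(expected)
        assert cm.evenness([10, 1], method="pielou") < 1.0


class TestRarefiedRichness:
    def test_full_sample_gives_richness(self):
        assert cm.rarefied_richness([50, 30, 20], 100) == pytest.approx(3.0)

    def test_single_draw_gives_one(self):
        assert cm.rarefied_richness([50, 30, 20], 1) == pytest.approx(1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            cm.rarefied_richness([5, 5], 11)
        with pytest.raises(ValueError):
            cm.rarefied_richness([5, 5], 0)

    def test_monte_carlo_oracle(self, rng):
        counts = np.array([50, 30, 20])
        draws = rng.multivariate_hypergeometric(counts, 10, size=100_000)
        mc = (draws > 0).sum(axis=1).mean()
        assert cm.rarefied_richness(counts, 10) == pytest.approx(mc, abs=0.01)

    def test_monotone_in_n(self):
        counts = [40, 25, 10, 3, 1]
        vals = [cm.rarefied_richness(counts, n) for n in range(1, 80)]
        assert np.all(np.diff(vals) >= -1e-12)


class TestAccumulationCurve:
    def test_single_species_constant(self, rng):
        curve = cm.accumulation_curve(["a"] * 12, n_perm=10, rng=rng)
        np.testing.assert_allclose(curve, 1.0)

    def test_endpoint_equals_total_richness(self, rng):
        labels = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        curve = cm.accumulation_curve(labels, n_perm=20, rng=rng)
        assert curve[-1] == pytest.approx(3.0)
        assert np.all(np.diff(curve) >= -1e-12)

    def test_matches_rarefaction_in_expectation(self, rng):
        counts = np.array([30, 15, 5])
        labels = np.repeat(["a", "b", "c"], counts)
        curve = cm.accumulation_curve(labels, n_perm=3000, rng=rng)
        for n in (5, 10, 25):
            assert curve[n - 1] == pytest.approx(
                cm.rarefied_richness(counts, n), abs=0.05
            )


def _month_fixture(specimen_table_factory):
    rows = []
    # site S1/S2 in G1; S3 in G2; two years, two months
    for year, m, site, sp, k in [
        (2014, 5, "S1", "Apis mellifera", 10),
        (2015, 5, "S1", "Apis mellifera", 30),
        (2014, 5, "S2", "Bombus impatiens", 4),
        (2015, 5, "S2", "Apis mellifera", 6),
        (2014, 6, "S1", "Apis mellifera", 2),
        (2014, 5, "S3", "Andrena nasonii", 8),
    ]:
        rows += [(sp, site, "T1", f"{year}-{m:02d}-10")] * k
    tab = specimen_table_factory(rows)
    grouping = SiteGrouping({"S1": "G1", "S2": "G1", "S3": "G2"})
    return tab, grouping


class TestMonthSummary:
    def test_two_year_average(self, specimen_table_factory):
        tab, grouping = _month_fixture(specimen_table_factory)
        out = cm.month_summary(build_month_matrix(tab), grouping)
        row = out[(out.site_group == "G1") & (out.period == 5)].iloc[0]
        # S1: (10+30)/2 = 20; S2: (4+6)/2 = 5; group mean = 12.5
        assert row["abundance"] == pytest.approx(12.5)

    def test_identical_years_equal_single_year(self, specimen_table_factory):
        rows = [("Apis mellifera", "S1", "T1", "2014-05-10")] * 4
        rows += [("Apis mellifera", "S1", "T1", "2015-05-10")] * 4
        tab = specimen_table_factory(rows)
        out = cm.month_summary(
            build_month_matrix(tab), SiteGrouping({"S1": "G1"})
        )
        row = out[out.period == 5].iloc[0]
        assert row["abundance"] == pytest.approx(4.0)
        assert row["richness"] == pytest.approx(1.0)

    def test_matches_two_step_oracle(self, default_sim):
        specimens, _, _, _ = default_sim
        from beemon.synthetic_data import SimConfig

        grouping = SiteGrouping(SimConfig().grouping_map())
        matrix = build_month_matrix(specimens)
        out = cm.month_summary(matrix, grouping)

        # brute-force oracle: loop per (site, month, year)
        recs = []
        for (site, year, month), row in matrix.counts.iterrows():
            c = row.to_numpy(float)
            recs.append({
                "site": site, "year": year, "month": month,
                "abundance": c.sum(),
                "richness": float((c > 0).sum()),
            })
        df = pd.DataFrame(recs)
        df["group"] = df["site"].map(grouping.mapping)
        oracle = (
            df.groupby(["site", "group", "month"])[["abundance", "richness"]]
            .mean()
            .groupby(["group", "month"])
            .mean()
        )
        for (g, m), row in oracle.iterrows():
            got = out[(out.site_group == g) & (out.period == m)].iloc[0]
            assert got["abundance"] == pytest.approx(row["abundance"])
            assert got["richness"] == pytest.approx(row["richness"])

    def test_zero_months_excluded_from_diversity_average(
        self, specimen_table_factory
    ):
        # one year has captures in May, the other has none at that site
        rows = [("Apis mellifera", "S1", "T1", "2014-05-10")] * 3
        rows += [("Bombus impatiens", "S1", "T1", "2014-05-11")] * 3
        rows += [("Apis mellifera", "S1", "T1", "2015-06-10")]
        tab = specimen_table_factory(rows)
        out = cm.month_summary(
            build_month_matrix(tab), SiteGrouping({"S1": "G1"})
        )
        may = out[out.period == 5].iloc[0]
        # diversity averaged over the single nonzero year only
        assert may["diversity"] == pytest.approx(2.0)
        # abundance averages zero months in: (6 + 0)/2
        assert may["abundance"] == pytest.approx(3.0)

    def test_zero_policy_zero(self, specimen_table_factory):
        rows = [("Apis mellifera", "S1", "T1", "2014-05-10")] * 3
        rows += [("Bombus impatiens", "S1", "T1", "2014-05-11")] * 3
        rows += [("Apis mellifera", "S1", "T1", "2015-06-10")]
        tab = specimen_table_factory(rows)
        out = cm.month_summary(
            build_month_matrix(tab), SiteGrouping({"S1": "G1"}),
            zero_policy="zero",
        )
        may = out[out.period == 5].iloc[0]
        assert may["diversity"] == pytest.approx(1.0)  # (2 + 0)/2


class TestYearSummary:
    def test_site_average_within_group(self, specimen_table_factory):
        rows = [("Apis mellifera", "S1", "T1", "2014-05-10")] * 10
        rows += [("Apis mellifera", "S2", "T1", "2014-05-10")] * 30
        tab = specimen_table_factory(rows)
        out = cm.year_summary(
            build_year_matrix(tab), SiteGrouping({"S1": "G1", "S2": "G1"})
        )
        row = out[out.period == 2014].iloc[0]
        assert row["abundance"] == pytest.approx(20.0)

    def test_single_site_passthrough(self, specimen_table_factory):
        rows = [("Apis mellifera", "S1", "T1", "2014-05-10")] * 5
        rows += [("Bombus impatiens", "S1", "T1", "2014-07-10")] * 5
        out = cm.year_summary(
            build_year_matrix(specimen_table_factory(rows)),
            SiteGrouping({"S1": "G1"}),
        )
        row = out.iloc[0]
        assert row["abundance"] == pytest.approx(10.0)
        assert row["richness"] == pytest.approx(2.0)
        assert row["diversity"] == pytest.approx(2.0)

    def test_matches_oracle(self, default_sim):
        specimens, _, _, _ = default_sim
        from beemon.synthetic_data import SimConfig

        grouping = SiteGrouping(SimConfig().grouping_map())
        matrix = build_year_matrix(specimens)
        out = cm.year_summary(matrix, grouping)
        df = matrix.counts.sum(axis=1).rename("abundance").reset_index()
        df["group"] = df["site_id"].map(grouping.mapping)
        oracle = df.groupby(["group", "year"])["abundance"].mean()
        for (g, y), val in oracle.items():
            got = out[(out.site_group == g) & (out.period == y)].iloc[0]
            assert got["abundance"] == pytest.approx(val)


class TestPercentChange:
    def test_reference_monthly_means(self):
        # April 21, July 168, overall 76 bees per site
        assert round(cm.percent_change(21, 168, 76)) == 193

    def test_no_change(self):
        assert cm.percent_change(5.0, 5.0, 123.0) == pytest.approx(0.0)

    def test_formula_oracle(self):
        assert cm.percent_change(10, 30, 20) == pytest.approx(100.0)

    def test_zero_overall_errors(self):
        with pytest.raises(ValueError):
            cm.percent_change(1, 2, 0)

    def test_sign_preserved(self):
        assert cm.percent_change(30, 10, 20) == pytest.approx(-100.0)


class TestYearlyCV:
    def test_constant_series(self):
        assert cm.yearly_cv([4, 4, 4]) == pytest.approx(0.0)

    def test_formula_oracle(self):
        # sd([10,20]) = 7.0711, mean 15 -> 47.14%
        assert cm.yearly_cv([10, 20]) == pytest.approx(100 * np.sqrt(50) / 15)

    def test_zero_mean_is_nan(self):
        assert np.isnan(cm.yearly_cv([-1, 1]))

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            cm.yearly_cv([5])


def test_month_label_permutation_equivariance(specimen_table_factory):
    """Relabeling months permutes summary rows identically."""
    rows = [("Apis mellifera", "S1", "T1", "2014-05-10")] * 3
    rows += [("Bombus impatiens", "S1", "T1", "2014-08-10")] * 7
    tab = specimen_table_factory(rows)
    swapped = [("Apis mellifera", "S1", "T1", "2014-08-10")] * 3
    swapped += [("Bombus impatiens", "S1", "T1", "2014-05-10")] * 7
    tab2 = specimen_table_factory(swapped)
    g = SiteGrouping({"S1": "G1"})
    a = cm.month_summary(build_month_matrix(tab), g).set_index("period")
    b = cm.month_summary(build_month_matrix(tab2), g).set_index("period")
    assert a.loc[5, "abundance"] == b.loc[8, "abundance"]
    assert a.loc[8, "abundance"] == b.loc[5, "abundance"]
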