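"""Incidence rates, quantile categorization, prevalence trends."""

import numpy as np
import pandas as pd
import pytest

from lifecourse import (
    cohort_census,
    generate_cohort,
    incidence_rates,
    prevalence_trend,
    quantile_categorize,
)
from lifecourse.incidence import age_band_label
from lifecourse.synthetic import AGE_BANDS

from conftest import events_frame


def brute_force_incidence(events, census, terms, period, age_groups, recurrent=False):
    """Independent person-by-person enumeration of events and person-years."""
    start, end = period
    cells = {}
    for term in terms:
        for band in age_groups:
            cells[(term, band)] = [0, 0.0]  # events, person-years
    for _, person in census.iterrows():
        pid, birth = person["person_id"], person["birth_year"]
        mine = events[events["person_id"] == pid]
        for term in terms:
            term_years = sorted(mine[mine["code"] == term]["year"])
            if recurrent:
                exit_year = end
                counted_years = [y for y in term_years if start <= y <= end]
            else:
                exit_year = min(term_years) if term_years else end
                counted_years = (
                    [term_years[0]] if term_years and start <= term_years[0] <= end else []
                )
            for y in counted_years:
                age = y - birth
                for band in age_groups:
                    if band[0] <= age <= band[1]:
                        cells[(term, band)][0] += 1
            for year in range(max(start, birth), min(end, exit_year) + 1):
                age = year - birth
                for band in age_groups:
                    if band[0] <= age <= band[1]:
                        cells[(term, band)][1] += 1.0
    return cells


class TestIncidenceRates:
    def test_no_events_gives_zero_ir_with_positive_person_years(self):
        census = pd.DataFrame({"person_id": range(5), "birth_year": [2000] * 5})
        events = events_frame([(0, 2000, 2012, "OTHER", "diagnosis")])
        table = incidence_rates(events, census, ["G473"], period=(2010, 2021))
        defined = table[table["ir_defined"]]
        assert (defined["ir_per_100k"] == 0).all()
        assert (defined["person_years"] > 0).all()
        assert table[~table["ir_defined"]]["ir_per_100k"].isna().all()

    def test_two_events_per_thousand_person_years_is_200(self):
        # 100 persons aged 10 in 2012, observed 2010-2019 within band 10-19
        census = pd.DataFrame({"person_id": range(100), "birth_year": [2000] * 100})
        events = events_frame(
            [(0, 2000, 2012, "X", "adversity"), (1, 2000, 2013, "X", "adversity")]
        )
        table = incidence_rates(
            events, census, ["X"], period=(2010, 2019), age_groups=[(10, 19)]
        )
        row = table.iloc[0]
        # 98 persons x 10 y + person 0: 3 y + person 1: 4 y = 987 person-years
        assert row["events"] == 2
        assert row["person_years"] == 987.0
        assert row["ir_per_100k"] == pytest.approx(2 / 987 * 100_000)

    def test_cells_match_person_by_person_enumeration(self):
        """Every (term, age-group) cell equals the brute-force oracle on a
        200-person synthetic cohort."""
        from lifecourse import default_cohort_spec

        spec = default_cohort_spec(n_individuals=200, seed=21)
        events = generate_cohort(spec)
        census = cohort_census(spec)
        terms = ["G473", "N05CH", "F515", "poverty"]
        period = (2010, 2021)
        table = incidence_rates(events, census, terms, period=period)
        oracle = brute_force_incidence(events, census, terms, period, AGE_BANDS)
        for (term, band), (n_ev, py) in oracle.items():
            row = table[
                (table["term"] == term) & (table["age_group"] == age_band_label(band))
            ].iloc[0]
            assert row["events"] == n_ev, (term, band)
            assert row["person_years"] == py, (term, band)

    def test_recurrent_convention_counts_every_event_without_exit(self):
        census = pd.DataFrame({"person_id": [0], "birth_year": [2000]})
        events = events_frame(
            [(0, 2000, 2011, "X", "adversity"), (0, 2000, 2013, "X", "adversity")]
        )
        first = incidence_rates(events, census, ["X"], period=(2010, 2021),
                                age_groups=[(10, 21)])
        recur = incidence_rates(events, census, ["X"], period=(2010, 2021),
                                age_groups=[(10, 21)], recurrent=True)
        assert first["events"].sum() == 1
        assert recur["events"].sum() == 2
        assert recur["person_years"].iloc[0] > first["person_years"].iloc[0]

    def test_person_years_conservation(self):
        """Summed risk time equals direct per-person integration (no events)."""
        census = pd.DataFrame({"person_id": range(30), "birth_year": range(1985, 2015)})
        events = events_frame([(0, 1985, 2000, "OTHER", "diagnosis")])
        period = (2010, 2021)
        table = incidence_rates(events, census, ["X"], period=period)
        direct = 0
        for _, p in census.iterrows():
            for year in range(max(period[0], p["birth_year"]), period[1] + 1):
                if 0 <= year - p["birth_year"] <= 44:
                    direct += 1
        assert table["person_years"].sum() == direct

    def test_inverted_period_rejected(self):
        census = pd.DataFrame({"person_id": [0], "birth_year": [2000]})
        with pytest.raises(ValueError, match="inverted"):
            incidence_rates(events_frame([]), census, ["X"], period=(2021, 2010))


class TestQuantileCategorize:
    @staticmethod
    def make_table(irs):
        return pd.DataFrame(
            {
                "term": ["X"] * len(irs),
                "age_group": [f"g{i}" for i in range(len(irs))],
                "events": 1,
                "person_years": 1000.0,
                "ir_per_100k": irs,
                "ir_defined": True,
            }
        )

    def test_five_distinct_irs_span_all_five_categories(self):
        out = quantile_categorize(self.make_table([1, 2, 3, 4, 5]), q=5)
        assert sorted(out["quantile"]) == [1, 2, 3, 4, 5]

    def test_constant_irs_collapse_to_single_category(self):
        out = quantile_categorize(self.make_table([3, 3, 3, 3]), q=5)
        assert out["quantile"].nunique() == 1

    def test_matches_rank_then_bin_oracle_on_random_vector(self, rng):
        irs = rng.uniform(0, 500, size=8).tolist()
        out = quantile_categorize(self.make_table(irs), q=5)
        ranks = pd.Series(irs).rank(method="min")
        expected = np.ceil(5 * ranks / len(irs)).astype(int)
        assert list(out["quantile"]) == list(expected)

    def test_monotone_higher_ir_never_lower_category(self, rng):
        irs = rng.uniform(0, 100, size=10)
        out = quantile_categorize(self.make_table(irs), q=5)
        order = np.argsort(irs)
        cats = out["quantile"].to_numpy()[order]
        assert (np.diff(cats.astype(int)) >= 0).all()

    def test_invariant_under_strictly_monotone_transform(self, rng):
        irs = rng.uniform(1, 100, size=7)
        a = quantile_categorize(self.make_table(irs.tolist()), q=5)
        b = quantile_categorize(self.make_table(np.log(irs).tolist()), q=5)
        assert list(a["quantile"]) == list(b["quantile"])

    def test_undefined_irs_get_no_category(self):
        table = self.make_table([1.0, 2.0, np.nan])
        table.loc[2, "ir_defined"] = False
        out = quantile_categorize(table, q=2)
        assert pd.isna(out.loc[2, "quantile"])


class TestPrevalenceTrend:
    @staticmethod
    def aggregate():
        return pd.DataFrame(
            {
                "year": [2010, 2011, 2012, 2013, 2014],
                "indicator": ["sleep"] * 5,
                "affected": [49, 10, 0, 25, 30],
                "population": [100, 1000, 500, 1000, 1500],
            }
        )

    def test_percent_scale(self):
        series = prevalence_trend(self.aggregate(), scale="percent")
        assert series.loc[series["year"] == 2010, "rate"].iloc[0] == pytest.approx(49.0)

    def test_zero_affected_gives_zero_rate(self):
        series = prevalence_trend(self.aggregate())
        assert series.loc[series["year"] == 2012, "rate"].iloc[0] == 0.0

    def test_rates_equal_independent_recomputation(self):
        agg = self.aggregate()
        series = prevalence_trend(agg, scale="per-1000")
        merged = series.merge(agg, on="year", suffixes=("", "_raw"))
        expected = merged["affected_raw"] / merged["population_raw"] * 1000
        assert np.allclose(merged["rate"], expected)

    def test_per_1000_is_ten_times_percent(self):
        per_k = prevalence_trend(self.aggregate(), scale="per-1000")
        pct = prevalence_trend(self.aggregate(), scale="percent")
        assert np.allclose(per_k["rate"], 10 * pct["rate"])

    def test_sorted_by_year(self):
        agg = self.aggregate().sample(frac=1, random_state=1)
        series = prevalence_trend(agg)
        assert list(series["year"]) == sorted(series["year"])

    def test_zero_population_rejected(self):
        agg = self.aggregate()
        agg.loc[0, "population"] = 0
        with pytest.raises(ValueError, match="population"):
            prevalence_trend(agg)
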