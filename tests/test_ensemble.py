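"""Tests for site classification, wind classes, matching and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airtails.ensemble import (AREA_TYPES, ENVIRONMENT_CATEGORIES,
                               STATION_TYPES, WIND_LABELS, beaufort_class,
                               classify_site, group_lambda_summary,
                               match_weather_station, scatter_table)
from airtails.errors import DataError
from airtails.synth import SuperstatConfig, gen_concentration_series
from airtails.tailfit import fit_site


class TestClassifySite:
    def test_urban_traffic(self):
        assert classify_site("traffic", "urban") == "urban traffic"

    def test_suburban_and_rural_traffic_merge(self):
        assert (classify_site("traffic", "suburban")
                == classify_site("traffic", "rural")
                == "suburban/rural traffic")

    def test_nine_pairs_collapse_to_seven_categories(self):
        labels = {classify_site(s, a)
                  for s, a in itertools.product(STATION_TYPES, AREA_TYPES)}
        assert len(labels) == 7
        assert labels == set(ENVIRONMENT_CATEGORIES)

    def test_case_insensitive(self):
        assert classify_site("Traffic", "URBAN") == "urban traffic"

    def test_unknown_types_rejected(self):
        with pytest.raises(DataError):
            classify_site("residential", "urban")

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.sampled_from(STATION_TYPES), st.sampled_from(AREA_TYPES))
    def test_total_on_domain(self, station, area):
        assert classify_site(station, area) in ENVIRONMENT_CATEGORIES


class TestBeaufort:
    @pytest.mark.parametrize("ws,label", [
        (0.0, "calm & light air"), (0.3, "calm & light air"),
        (1.5, "calm & light air"), (2.0, "light breeze"),
        (3.3, "light breeze"), (4.0, "gentle breeze"),
        (5.4, "gentle breeze"), (6.0, "moderate breeze"),
        (7.9, "moderate breeze")])
    def test_boundaries(self, ws, label):
        wc = beaufort_class(ws)
        assert wc.label == label and wc.in_scale

    def test_sweep_yields_exactly_four_labels(self):
        labels = {beaufort_class(ws).label for ws in np.arange(0.0, 7.9, 0.01)}
        assert labels == set(WIND_LABELS)
        assert len(labels) == 4

    def test_above_scale_flagged(self):
        wc = beaufort_class(9.0)
        assert not wc.in_scale and wc.label not in WIND_LABELS

    def test_negative_speed_rejected(self):
        with pytest.raises(DataError):
            beaufort_class(-0.1)


class TestMatchWeatherStation:
    def test_within_radius_matched(self):
        assert match_weather_station((50.0, 10.0), [(50.09, 10.05)]) == 0

    def test_boundary_excluded(self):
        assert match_weather_station((50.0, 10.0), [(50.10, 10.0)]) is None

    def test_nearest_wins(self):
        stations = [(50.05, 10.0), (50.02, 10.0)]
        assert match_weather_station((50.0, 10.0), stations) == 1

    def test_empty_station_list(self):
        assert match_weather_station((50.0, 10.0), []) is None


def _dummy_fit(site, lam, q=1.2):
    """Minimal SiteFit stand-in for summary tests (synthetic, no real fit)."""
    from airtails.candidates import CandidateFit
    from airtails.tailfit import SiteFit, TailCut
    cut = TailCut(0.0, np.array([1.0]), 1)
    cf = CandidateFit("qexponential", {"q": q, "lam": lam}, -1.0, 1)
    return SiteFit(site, "no2", cut, {"qexponential": cf}, "qexponential",
                   q, lam, 1.0, 1.0)


class TestGroupSummary:
    def test_single_site_group(self):
        fits = [_dummy_fit("s1", 2.0)]
        (summary,) = group_lambda_summary(fits, {"s1": "A"})
        assert summary.median_lambda == 2.0
        assert summary.iqr == (2.0, 2.0)
        assert summary.n_sites == 1

    def test_order_statistics_oracle(self):
        fits = [_dummy_fit(f"s{i}", lam) for i, lam in enumerate([1, 2, 3, 4, 5])]
        groups = {f.site_code: "A" for f in fits}
        (summary,) = group_lambda_summary(fits, groups)
        assert summary.median_lambda == 3.0
        assert summary.iqr == (2.0, 4.0)

    def test_groups_ranked_by_median_ascending(self):
        fits, groups = [], {}
        for label, lams in [("C", [5, 6, 7]), ("A", [1, 2, 3]), ("B", [3, 4, 5])]:
            for i, lam in enumerate(lams):
                code = f"{label}{i}"
                fits.append(_dummy_fit(code, float(lam)))
                groups[code] = label
        labels = [s.label for s in group_lambda_summary(fits, groups)]
        assert labels == ["A", "B", "C"]

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            group_lambda_summary([], {})

    def test_quantiles_match_sorted_brute_force_odd_n(self, rng):
        lams = rng.exponential(1.0, 21)
        fits = [_dummy_fit(f"s{i}", lam) for i, lam in enumerate(lams)]
        (s,) = group_lambda_summary(fits, {f.site_code: "A" for f in fits})
        assert s.median_lambda == sorted(lams)[10]


class TestScatterTable:
    def test_log10_lambda(self):
        df = scatter_table([_dummy_fit("s1", 100.0)])
        assert df["log10_lambda"].iloc[0] == pytest.approx(2.0)

    def test_row_count_equals_number_of_fits(self):
        fits = [_dummy_fit(f"s{i}", 1.0 + i) for i in range(5)]
        assert len(scatter_table(fits)) == 5

    def test_round_trips_through_csv(self, tmp_path):
        fits = [_dummy_fit(f"s{i}", 0.5 + i) for i in range(4)]
        df = scatter_table(fits, {f.site_code: "urban traffic" for f in fits})
        path = tmp_path / "scatter.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["q"], df["q"])
        assert np.allclose(back["log10_lambda"], df["log10_lambda"])
        assert list(back["category"]) == list(df["category"])


def test_planted_lambda_ordering_preserved_by_fits():
    """Sites generated with lower rate scale (more polluted) must keep a
    lower fitted-lambda median than cleaner sites."""
    fits, groups = [], {}
    for label, theta, n in [("urban traffic", 0.02, 3), ("rural background", 0.3, 3)]:
        for i in range(n):
            cfg = SuperstatConfig(a=2.0, theta=theta, n_hours=12000, lod=0.01,
                                  seed=1000 + 10 * i + int(theta * 100))
            code = f"{label[:3]}{i}"
            series = gen_concentration_series(cfg, site_code=code)
            fits.append(fit_site(series))
            groups[code] = label
    summaries = group_lambda_summary(fits, groups)
    assert [s.label for s in summaries] == ["urban traffic", "rural background"]
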