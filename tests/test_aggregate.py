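"""Cohort filters, location grouping, and the two aggregation levels."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emotraj.aggregate import (
    DEFAULT_REGIONS,
    DEFAULT_WINDOW,
    CohortError,
    StudyWindow,
    assign_group,
    assign_user_groups,
    by_day,
    descriptives,
    filter_cohort,
    person_day,
)


class TestStudyWindow:
    def test_event_must_lie_inside_window(self):
        with pytest.raises(CohortError):
            StudyWindow(date(2020, 2, 1), date(2020, 2, 6), date(2020, 1, 23))

    def test_default_window(self):
        assert DEFAULT_WINDOW.start == date(2020, 1, 9)
        assert DEFAULT_WINDOW.event == date(2020, 1, 23)
        assert DEFAULT_WINDOW.end == date(2020, 2, 6)


class TestAssignGroup:
    def test_region_label(self):
        assert assign_group(region_label="Wuhan") == "wuhan"
        assert assign_group(region_label="湖北") == "excluded"

    def test_coordinates(self):
        assert assign_group(lat=30.6, lon=114.3) == "wuhan"        # in Wuhan box
        assert assign_group(lat=39.9, lon=116.4) == "non_hubei"    # Beijing-ish
        # inside Hubei but outside Wuhan: other locked-down cities, excluded
        assert assign_group(lat=32.0, lon=112.1) == "excluded"

    def test_unlocatable_is_excluded(self):
        assert assign_group() == "excluded"

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(CohortError):
            assign_group(lat=95.0, lon=10.0)

    def test_user_groups_use_post_event_geotags_only(self):
        posts = pd.DataFrame(
            {
                "user_id": ["a", "a", "b", "b", "c"],
                "date": [date(2020, 1, 10), date(2020, 1, 25),
                         date(2020, 1, 10), date(2020, 1, 25), date(2020, 1, 25)],
                # user a: Wuhan before, Beijing after -> non_hubei
                # user b: geotag only before the event -> excluded
                # user c: Wuhan after -> wuhan
                "lat": [30.6, 39.9, 30.6, np.nan, 30.6],
                "lon": [114.3, 116.4, 114.3, np.nan, 114.3],
            }
        )
        groups = assign_user_groups(posts, DEFAULT_REGIONS, date(2020, 1, 23))
        assert groups["a"] == "non_hubei"
        assert groups["b"] == "excluded"
        assert groups["c"] == "wuhan"


def _scored(rows):
    return pd.DataFrame(
        rows, columns=["post_id", "user_id", "date", "valence", "arousal"]
    )


class TestFilterCohort:
    def test_hand_enumerated_audit(self):
        nan = float("nan")
        rows = [
            # u1: healthy pre+post user (4 posts)
            ("p1", "u1", date(2020, 1, 10), 0.5, 2.0),
            ("p2", "u1", date(2020, 1, 25), 0.2, 2.5),
            ("p3", "u1", date(2020, 1, 26), 0.1, 2.1),
            ("p4", "u1", date(2020, 1, 12), -0.3, 1.0),
            # out of window
            ("p5", "u1", date(2020, 2, 20), 0.9, 3.0),
            # missing score
            ("p6", "u1", date(2020, 1, 20), nan, nan),
            # u2: single post
            ("p7", "u2", date(2020, 1, 15), 0.4, 2.0),
            # u3: posts only after the event
            ("p8", "u3", date(2020, 1, 24), 0.4, 2.0),
            ("p9", "u3", date(2020, 1, 25), 0.6, 2.2),
            ("p10", "u3", date(2020, 1, 26), 0.1, 2.4),
        ]
        out, audit = filter_cohort(_scored(rows), DEFAULT_WINDOW, "dataset2")
        assert audit["outside_window"] == 1
        assert audit["missing_score"] == 1
        assert audit["single_post_user"] == 1
        assert audit["no_pre_post_user"] == 3
        assert audit["survivors"] == 4
        assert set(out["user_id"]) == {"u1"}
        removed = sum(v for k, v in audit.items() if k not in ("input", "survivors"))
        assert removed + audit["survivors"] == audit["input"] == len(rows)

    def test_event_day_counts_as_post_event(self):
        rows = [
            ("p1", "u1", date(2020, 1, 22), 0.1, 2.0),
            ("p2", "u1", date(2020, 1, 23), 0.2, 2.0),
        ]
        out, audit = filter_cohort(_scored(rows), DEFAULT_WINDOW, "dataset2")
        assert audit["survivors"] == 2

    def test_dataset1_rules_keep_single_post_users(self):
        rows = [("p1", "u1", date(2020, 1, 15), 0.1, 2.0)]
        out, audit = filter_cohort(_scored(rows), DEFAULT_WINDOW, "dataset1")
        assert audit["survivors"] == 1

    def test_unknown_rules(self):
        with pytest.raises(CohortError):
            filter_cohort(_scored([]), DEFAULT_WINDOW, "dataset3")


class TestAggregationLevels:
    def test_person_day_averages_within_user_date(self):
        rows = [
            ("p1", "u1", date(2020, 1, 10), 1.0, 2.0),
            ("p2", "u1", date(2020, 1, 10), 3.0, 4.0),
        ]
        out = person_day(_scored(rows))
        assert len(out) == 1
        assert out.loc[0, "valence"] == 2.0
        assert out.loc[0, "n_posts"] == 2

    def test_by_day_is_user_weighted_not_post_weighted(self):
        rows = [("pA%d" % i, "uA", date(2020, 1, 10), 0.0, 2.0) for i in range(10)]
        rows.append(("pB", "uB", date(2020, 1, 10), 2.0, 4.0))
        pdays = person_day(_scored(rows))
        days = by_day(pdays)
        # two-stage: mean of person-day means (0 and 2), not of the 11 posts
        assert days.loc[0, "valence"] == 1.0
        assert days.loc[0, "n_users"] == 2

    def test_post_weighted_option_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"p{i}", f"u{rng.integers(4)}", date(2020, 1, 10 + int(rng.integers(3))),
             float(rng.normal()), float(abs(rng.normal()) + 1))
            for i in range(60)
        ]
        frame = _scored(rows)
        pdays = person_day(frame)
        days = by_day(pdays, weights="post")
        oracle = frame.groupby("date")["valence"].mean()
        for rec in days.itertuples(index=False):
            assert rec.valence == pytest.approx(oracle[rec.date], abs=1e-12)

    def test_balanced_panel_reduces_to_plain_mean(self):
        # every user posts exactly once per day -> two-stage == one-stage
        rows = [
            (f"p{u}{d}", f"u{u}", date(2020, 1, 10 + d), float(u + d), 2.0)
            for u in range(3) for d in range(4)
        ]
        frame = _scored(rows)
        days = by_day(person_day(frame))
        oracle = frame.groupby("date")["valence"].mean()
        for rec in days.itertuples(index=False):
            assert rec.valence == pytest.approx(oracle[rec.date], abs=1e-12)


class TestDescriptives:
    def _pdays(self, values, group="non_hubei"):
        return pd.DataFrame(
            {
                "user_id": [f"u{i}" for i in range(len(values))],
                "group": group,
                "date": date(2020, 1, 10),
                "valence": values,
                "arousal": values,
            }
        )

    def test_moments_match_direct_formula_on_six_numbers(self):
        x = np.array([0.3, -1.2, 0.8, 1.4, -0.5, 0.1])
        out = descriptives(self._pdays(list(x)), outcomes=("valence",))
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(m, abs=1e-12)
        assert row["sd"] == pytest.approx(np.std(x, ddof=1), abs=1e-12)
        assert row["skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert row["kurtosis"] == pytest.approx(m4 / m2**2 - 3.0, abs=1e-12)

    def test_constant_data_reported_as_missing_with_flag(self):
        out = descriptives(self._pdays([1.0] * 5), outcomes=("valence",))
        row = out.iloc[0]
        assert row["sd"] == 0.0
        assert np.isnan(row["skewness"]) and np.isnan(row["kurtosis"])
        assert not row["normality_ok"]

    def test_large_normal_sample_is_asymptotically_symmetric(self):
        rng = np.random.default_rng(77)
        out = descriptives(
            self._pdays(list(rng.normal(0, 1, 10_000))), outcomes=("valence",)
        )
        row = out.iloc[0]
        assert abs(row["skewness"]) < 0.1
        assert abs(row["kurtosis"]) < 0.2
        assert row["normality_ok"]

    def test_single_row_group_rejected(self):
        with pytest.raises(CohortError):
            descriptives(self._pdays([1.0]))
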