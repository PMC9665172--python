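"""Cohort filtering, location grouping, and person-day / by-day aggregation.

The analysis window runs from two weeks before to two weeks after a
lockdown announcement (defaults: 2020-01-09 to 2020-02-06, event
2020-01-23).  Users are grouped by their post-event geotags into a
locked-down group (Wuhan, dummy code 1) and a comparison group outside
the affected province (non-Hubei, code 0); users locatable only inside
Hubei-but-not-Wuhan, or not locatable at all, are excluded because their
lockdown status is ambiguous.

Two aggregation levels are produced.  The *person-day* score is the mean
of a user's scored posts on one date (the level-1 observation of the
growth models).  The *by-day* score averages person-day scores across
users — each user counts once per day regardless of how many posts they
made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

GROUP_CODE = {"wuhan": 1, "non_hubei": 0}
SKEWNESS_NORMALITY_BOUNDS = (-2.0, 2.0)
KURTOSIS_NORMALITY_BOUNDS = (-7.0, 7.0)


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class StudyWindow:
    start: date
    end: date
    event: date

    def __post_init__(self) -> None:
        if not (self.start <= self.event <= self.end):
            raise CohortError(
                f"study window requires start <= event <= end, got "
                f"{self.start} / {self.event} / {self.end}"
            )

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end


DEFAULT_WINDOW = StudyWindow(date(2020, 1, 9), date(2020, 2, 6), date(2020, 1, 23))


@dataclass(frozen=True)
class BoundingBox:
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: float, lon: float) -> bool:
        return self.lat_min <= lat <= self.lat_max and self.lon_min <= lon <= self.lon_max


@dataclass(frozen=True)
class RegionConfig:
    """Named bounding boxes: a Wuhan box nested in a Hubei box.

    ``labels`` maps free-text region labels to one of "wuhan", "hubei"
    or "other".  Real administrative polygons are out of scope; boxes
    are adequate for synthetic data and honest about the imprecision of
    user-selectable geotags.
    """

    wuhan: BoundingBox
    hubei: BoundingBox
    labels: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            wuhan=BoundingBox(**raw["wuhan"]),
            hubei=BoundingBox(**raw["hubei"]),
            labels={str(k).lower(): v for k, v in raw.get("labels", {}).items()},
        )


# Approximate administrative extents; the non-Hubei side is "anywhere
# outside the Hubei box".
DEFAULT_REGIONS = RegionConfig(
    wuhan=BoundingBox(29.97, 31.36, 113.70, 115.08),
    hubei=BoundingBox(29.03, 33.28, 108.36, 116.13),
    labels={"wuhan": "wuhan", "武汉": "wuhan", "hubei": "hubei", "湖北": "hubei"},
)


def assign_group(
    lat: float | None = None,
    lon: float | None = None,
    region_label: str | None = None,
    regions: RegionConfig = DEFAULT_REGIONS,
) -> str:
    """Group for one record: "wuhan", "non_hubei", or "excluded".

    A region label, when present and recognized, takes precedence over
    coordinates.  Coordinates inside the Wuhan box map to "wuhan",
    inside Hubei-but-not-Wuhan to "excluded" (other Hubei cities were
    locked down too), outside Hubei to "non_hubei".  Unlocatable records
    are "excluded".
    """
    if region_label:
        kind = regions.labels.get(str(region_label).lower())
        if kind == "wuhan":
            return "wuhan"
        if kind == "hubei":
            return "excluded"
        if kind == "other":
            return "non_hubei"
    if lat is not None and lon is not None and not (np.isnan(lat) or np.isnan(lon)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise CohortError(f"geotag out of range: lat={lat}, lon={lon}")
        if regions.wuhan.contains(lat, lon):
            return "wuhan"
        if regions.hubei.contains(lat, lon):
            return "excluded"
        return "non_hubei"
    return "excluded"


def assign_user_groups(
    posts: pd.DataFrame,
    regions: RegionConfig = DEFAULT_REGIONS,
    event_date: date = DEFAULT_WINDOW.event,
) -> pd.Series:
    """Per-user group from post-event locatable posts.

    Only posts dated on/after the event are informative: movement out of
    the locked-down city was no longer possible, so post-event geotags
    pin users down.  A user with any post-event record placing them in
    Hubei-but-not-Wuhan is excluded; otherwise any Wuhan record makes
    the user "wuhan", any non-Hubei record "non_hubei"; users with no
    locatable post-event record are excluded.
    """
    post_event = posts[pd.to_datetime(posts["date"]).dt.date >= event_date]
    groups: dict[str, str] = {}
    for user_id, chunk in post_event.groupby("user_id"):
        seen = set()
        for rec in chunk.itertuples(index=False):
            lat = getattr(rec, "lat", None)
            lon = getattr(rec, "lon", None)
            label = getattr(rec, "region_label", None)
            if label is None or (isinstance(label, float) and np.isnan(label)):
                label = None
            locatable = label is not None or (
                lat is not None and lon is not None
                and not (np.isnan(lat) or np.isnan(lon))
            )
            if not locatable:
                continue  # uninformative record, not disqualifying
            seen.add(assign_group(lat=lat, lon=lon, region_label=label,
                                  regions=regions))
        if "excluded" in seen and ("wuhan" in seen or "non_hubei" in seen):
            # ambiguous or partly-Hubei trail: play safe
            groups[user_id] = "excluded"
        elif "wuhan" in seen:
            groups[user_id] = "wuhan"
        elif "non_hubei" in seen:
            groups[user_id] = "non_hubei"
        else:
            groups[user_id] = "excluded"
    out = pd.Series(groups, name="group")
    out.index.name = "user_id"
    return out


def filter_cohort(
    scores: pd.DataFrame,
    window: StudyWindow = DEFAULT_WINDOW,
    rules: str = "dataset2",
) -> tuple[pd.DataFrame, dict]:
    """Apply the study's filtering rules to a scored-post table.

    Both rule sets retain posts inside the window and drop posts with
    missing scores.  "dataset2" additionally emulates the longitudinal
    cohort: users with a single scored post are dropped, then users
    lacking at least one scored post before the event date and one on or
    after it.  ("Before" means date < event; the event date itself is
    post-event — the lockdown took effect that day.)

    Returns the filtered table and an audit dict whose removal counts
    plus survivors sum to the input size.
    """
    if rules not in {"dataset1", "dataset2"}:
        raise CohortError(f"unknown cohort rules {rules!r}")
    n_input = len(scores)
    dates = pd.to_datetime(scores["date"]).dt.date
    in_window = dates.map(window.contains)
    n_out_window = int((~in_window).sum())
    frame = scores[in_window]

    missing = frame["valence"].isna() | frame["arousal"].isna()
    n_missing = int(missing.sum())
    frame = frame[~missing]

    audit = {
        "input": n_input,
        "outside_window": n_out_window,
        "missing_score": n_missing,
    }
    if rules == "dataset2":
        post_counts = frame.groupby("user_id")["post_id"].count()
        single = post_counts[post_counts <= 1].index
        n_single = int(frame["user_id"].isin(single).sum())
        frame = frame[~frame["user_id"].isin(single)]

        fdates = pd.to_datetime(frame["date"]).dt.date
        pre_users = set(frame.loc[fdates < window.event, "user_id"])
        post_users = set(frame.loc[fdates >= window.event, "user_id"])
        keep_users = pre_users & post_users
        n_prepost = int((~frame["user_id"].isin(keep_users)).sum())
        frame = frame[frame["user_id"].isin(keep_users)]
        audit["single_post_user"] = n_single
        audit["no_pre_post_user"] = n_prepost
    audit["survivors"] = len(frame)
    return frame.reset_index(drop=True), audit


def person_day(scores: pd.DataFrame) -> pd.DataFrame:
    """Average scored posts within user x date.

    Returns columns user_id, date, valence, arousal, n_posts (plus group
    and location code when a ``group`` column is present).
    """
    frame = scores.dropna(subset=["valence", "arousal"])
    keys = ["user_id", "date"]
    if "group" in frame.columns:
        keys = ["user_id", "group", "date"]
    out = (
        frame.groupby(keys, sort=True)
        .agg(valence=("valence", "mean"), arousal=("arousal", "mean"),
             n_posts=("post_id", "count"))
        .reset_index()
    )
    if "group" in out.columns:
        out["location"] = out["group"].map(GROUP_CODE)
    return out


def by_day(
    person_days: pd.DataFrame,
    grouped: bool = False,
    weights: str = "user",
) -> pd.DataFrame:
    """Average person-day scores within date (optionally within group).

    ``weights="user"`` (default) gives each user one vote per day — the
    two-stage scheme of the study.  ``weights="post"`` weights person-day
    means by each user's post count instead.
    """
    if weights not in {"user", "post"}:
        raise CohortError(f"unknown weighting {weights!r}")
    keys = ["group", "date"] if grouped else ["date"]

    def _agg(chunk: pd.DataFrame) -> pd.Series:
        w = chunk["n_posts"].to_numpy(float) if weights == "post" else np.ones(len(chunk))
        return pd.Series(
            {
                "valence": float(np.average(chunk["valence"], weights=w)),
                "arousal": float(np.average(chunk["arousal"], weights=w)),
                "n_users": int(len(chunk)),
            }
        )

    out = person_days.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n_users"] = out["n_users"].astype(int)
    return out


def descriptives(
    person_days: pd.DataFrame,
    outcomes: tuple[str, ...] = ("valence", "arousal"),
    by_group: bool = True,
) -> pd.DataFrame:
    """Distributional summary of person-day scores per outcome (per group).

    Reports unique-user count, mean, SD (ddof=1), moment-based sample
    skewness g1 and excess kurtosis g2, and a flag for whether both fall
    inside the conventional normality-acceptability bounds (|skew| <= 2,
    |excess kurtosis| <= 7).  Constant data has SD 0 and undefined
    shape statistics, reported as NaN with the flag unset.
    """
    groups = person_days.groupby("group") if by_group and "group" in person_days.columns \
        else [("all", person_days)]
    rows = []
    for gname, chunk in groups:
        if len(chunk) < 2:
            raise CohortError(f"group {gname!r} has fewer than 2 person-day rows")
        for outcome in outcomes:
            x = chunk[outcome].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1))
            if sd == 0:
                skew = kurt = float("nan")
                normal_ok = False
            else:
                skew = float(stats.skew(x, bias=True))
                kurt = float(stats.kurtosis(x, fisher=True, bias=True))
                normal_ok = (
                    SKEWNESS_NORMALITY_BOUNDS[0] <= skew <= SKEWNESS_NORMALITY_BOUNDS[1]
                    and KURTOSIS_NORMALITY_BOUNDS[0] <= kurt <= KURTOSIS_NORMALITY_BOUNDS[1]
                )
            rows.append(
                {
                    "outcome": outcome,
                    "group": gname,
                    "n_users": int(chunk["user_id"].nunique()),
                    "n_person_days": len(chunk),
                    "mean": float(np.mean(x)),
                    "sd": sd,
                    "skewness": skew,
                    "kurtosis": kurt,
                    "normality_ok": normal_ok,
                }
            )
    return pd.DataFrame(rows)
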