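"""Raw post parsing and repost-aware text cleaning.

Microblog reposts concatenate the reposting user's own comment with the
comments of prior users in the repost chain, delimited by
``//@username:`` markers (both ASCII ``:`` and full-width ``：`` occur).
Only the reposting user's own comment carries that user's emotion, so
cleaning keeps the text before the first delimiter.  When the reposting
user added nothing, the prior users' comments are used instead — users
tend to repost only what they agree with — and the record is flagged
``used_fallback``.

After repost handling, hashtag markers, @-mentions and web links are
stripped.  Hashtags on the platform are paired markers (``#...#``); by
default the markers are removed but the interior text is kept, since
interior words (e.g. words of encouragement inside a campaign tag) are
ordinary emotional content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone, tzinfo
from pathlib import Path
from typing import Optional

import pandas as pd

CHINA_TZ = timezone(timedelta(hours=8))

# "//@" + username (no whitespace/colon) + ":" or full-width colon
_REPOST_DELIM = re.compile(r"//@[^\s:：]*[:：]")
_URL = re.compile(r"(?:https?://\S+|www\.\S+|\bt\.cn/\S+)")
_MENTION = re.compile(r"@[^\s:：#@]+")
_PAIRED_HASHTAG = re.compile(r"#([^#]*)#")


class PostRecordError(ValueError):
    """A single raw post record that cannot be parsed."""


@dataclass(frozen=True)
class RawPost:
    post_id: str
    user_id: str
    timestamp: str | datetime
    text: str
    is_repost: bool = False
    lat: Optional[float] = None
    lon: Optional[float] = None
    region_label: Optional[str] = None


@dataclass(frozen=True)
class CleanPost:
    post_id: str
    user_id: str
    date: date
    content: str
    used_fallback: bool = False


@dataclass(frozen=True)
class CleaningRules:
    """Configuration for text cleaning.

    tz: civil time zone used to bucket timestamps into calendar dates
        (UTC+8 by default — the study days are China-local).
    keep_hashtag_text: keep the interior of paired ``#...#`` tags.
    """

    tz: tzinfo = field(default=CHINA_TZ)
    keep_hashtag_text: bool = True


def split_repost(text: str) -> tuple[str, str]:
    """Split repost text into (own_comment, prior_comments).

    ``own_comment`` is the (stripped) text before the first ``//@user:``
    delimiter; ``prior_comments`` concatenates all delimited prior-user
    segments, markup and usernames removed, in the order they appear.
    Text without any delimiter returns ``(text, "")``.
    """
    parts = _REPOST_DELIM.split(text)
    own = parts[0].strip()
    prior = " ".join(p.strip() for p in parts[1:] if p.strip())
    return own, prior


def strip_noise(text: str, rules: CleaningRules = CleaningRules()) -> str:
    """Remove URLs, @-mentions and hashtag markers; collapse whitespace."""
    text = _URL.sub(" ", text)
    text = _MENTION.sub(" ", text)
    if rules.keep_hashtag_text:
        text = _PAIRED_HASHTAG.sub(lambda m: " " + m.group(1) + " ", text)
    else:
        text = _PAIRED_HASHTAG.sub(" ", text)
    text = text.replace("#", " ")
    return " ".join(text.split())


def _to_local_date(timestamp: str | datetime, tz: tzinfo) -> date:
    ts = pd.Timestamp(timestamp)
    if ts is pd.NaT:
        raise PostRecordError(f"unparseable timestamp {timestamp!r}")
    if ts.tzinfo is not None:
        ts = ts.tz_convert(tz)
    # naive timestamps are taken as already being civil local time
    return ts.date()


def clean_post(raw: RawPost, rules: CleaningRules = CleaningRules()) -> CleanPost:
    """Clean one raw post into a CleanPost.

    For reposts the content is the reposting user's own comment when its
    whitespace-stripped form is non-empty, otherwise the prior users'
    comments with ``used_fallback=True``.  Originals pass their full text
    through.  Noise stripping (URLs, mentions, hashtag markers) is then
    applied and the timestamp is bucketed to a calendar date in the
    configured time zone.
    """
    try:
        day = _to_local_date(raw.timestamp, rules.tz)
    except (ValueError, OverflowError, TypeError) as exc:
        raise PostRecordError(
            f"post {raw.post_id!r}: unparseable timestamp {raw.timestamp!r}"
        ) from exc
    text = raw.text if isinstance(raw.text, str) else ""
    used_fallback = False
    if raw.is_repost:
        own, prior = split_repost(text)
        if own.strip():
            content = own
        else:
            content = prior
            used_fallback = True
    else:
        content = text
    content = strip_noise(content, rules)
    return CleanPost(str(raw.post_id), str(raw.user_id), day, content, used_fallback)


def clean_posts(
    posts: pd.DataFrame, rules: CleaningRules = CleaningRules()
) -> tuple[pd.DataFrame, list[str]]:
    """Clean a batch of raw posts.

    ``posts`` must have columns post_id, user_id, timestamp, text,
    is_repost (lat/lon/region_label optional and passed through).
    Returns the CleanPost table and a list of record-level error
    messages; bad records are reported, not fatal to the batch.
    """
    if posts["post_id"].duplicated().any():
        dupes = posts.loc[posts["post_id"].duplicated(), "post_id"].tolist()
        raise PostRecordError(f"duplicate post ids: {dupes[:5]}")
    rows, errors = [], []
    passthrough = [c for c in ("lat", "lon", "region_label") if c in posts.columns]
    for rec in posts.itertuples(index=False):
        raw = RawPost(
            post_id=rec.post_id,
            user_id=rec.user_id,
            timestamp=rec.timestamp,
            text=rec.text,
            is_repost=bool(rec.is_repost),
        )
        try:
            cp = clean_post(raw, rules)
        except PostRecordError as exc:
            errors.append(str(exc))
            continue
        row = {
            "post_id": cp.post_id,
            "user_id": cp.user_id,
            "date": cp.date,
            "content": cp.content,
            "used_fallback": cp.used_fallback,
        }
        for c in passthrough:
            row[c] = getattr(rec, c)
        rows.append(row)
    return pd.DataFrame(rows), errors


def read_posts(path: str | Path) -> pd.DataFrame:
    """Read raw posts from JSON-lines (.jsonl/.json) or CSV."""
    path = Path(path)
    if path.suffix in {".jsonl", ".json"}:
        frame = pd.read_json(path, lines=True, dtype={"post_id": str, "user_id": str})
    else:
        frame = pd.read_csv(path, dtype={"post_id": str, "user_id": str})
    required = {"post_id", "user_id", "timestamp", "text", "is_repost"}
    missing = required - set(frame.columns)
    if missing:
        raise PostRecordError(f"post file {path} missing columns {sorted(missing)}")
    frame["text"] = frame["text"].fillna("")
    return frame


def write_posts(posts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".jsonl", ".json"}:
        posts.to_json(path, orient="records", lines=True, force_ascii=False)
    else:
        posts.to_csv(path, index=False)
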