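"""Post-level valence/arousal scoring and emotion-map summaries.

Each post's score is the frequency-weighted average of its matched
emotion words: valence = sum(c_w * v_w) / sum(c_w) over matched words w
with occurrence counts c_w, and likewise for arousal.  A post with no
lexicon match has missing scores.  Posts are classified into circumplex
quadrants by the sign of valence (pleasant > 0 > unpleasant) and the
position of arousal relative to the scale midpoint 4 (high > 4 > low);
posts exactly neutral in valence or exactly at arousal 4 form a residual
class.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cleaning import CleanPost
from .lexicon import Lexicon, match_lexicon_tokens

QUADRANTS = (
    "pleasant_low",
    "pleasant_high",
    "unpleasant_low",
    "unpleasant_high",
    "neutral_or_moderate",
)

AROUSAL_MIDPOINT = 4.0


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class PostScore:
    post_id: str
    valence: float  # NaN when no emotion word matched
    arousal: float
    n_emotion_tokens: int
    token_counts: Counter

    @property
    def missing(self) -> bool:
        return self.n_emotion_tokens == 0


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit of arousal on (1, valence, valence^2)."""

    intercept: float
    linear: float
    quadratic: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    df: tuple[int, int]
    n: int

    def predict(self, valence: np.ndarray) -> np.ndarray:
        v = np.asarray(valence, dtype=float)
        return self.intercept + self.linear * v + self.quadratic * v * v


def score_text(content: str, lexicon: Lexicon) -> tuple[float, float, Counter]:
    """Weighted-average (valence, arousal, token counts) for cleaned text."""
    counts = match_lexicon_tokens(content, lexicon)
    total = sum(counts.values())
    if total == 0:
        return math.nan, math.nan, counts
    valence = sum(c * lexicon[w].valence for w, c in counts.items()) / total
    arousal = sum(c * lexicon[w].arousal for w, c in counts.items()) / total
    return valence, arousal, counts


def score_post(clean: CleanPost, lexicon: Lexicon) -> PostScore:
    if len(lexicon) == 0:
        raise ScoringError("cannot score against an empty lexicon")
    valence, arousal, counts = score_text(clean.content, lexicon)
    return PostScore(clean.post_id, valence, arousal, sum(counts.values()), counts)


def classify_quadrant(valence: float, arousal: float) -> str:
    """Circumplex quadrant of a non-missing (valence, arousal) score.

    Strict inequalities define the four quadrants; scores exactly neutral
    in valence (0) or exactly at moderate arousal (4) fall in the
    residual ``neutral_or_moderate`` class.
    """
    if math.isnan(valence) or math.isnan(arousal):
        raise ScoringError(
            "cannot classify a missing score; filter unmatched posts upstream"
        )
    if valence == 0 or arousal == AROUSAL_MIDPOINT:
        return "neutral_or_moderate"
    if valence > 0:
        return "pleasant_high" if arousal > AROUSAL_MIDPOINT else "pleasant_low"
    return "unpleasant_high" if arousal > AROUSAL_MIDPOINT else "unpleasant_low"


def score_posts(clean: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Score a CleanPost table.

    Returns a DataFrame with columns post_id, user_id, date, valence,
    arousal, n_emotion_tokens, token_counts (a dict per row), quadrant
    (None for missing scores); lat/lon/region_label pass through if
    present.
    """
    if len(lexicon) == 0:
        raise ScoringError("cannot score against an empty lexicon")
    rows = []
    passthrough = [c for c in ("lat", "lon", "region_label") if c in clean.columns]
    for rec in clean.itertuples(index=False):
        valence, arousal, counts = score_text(rec.content, lexicon)
        n_tokens = sum(counts.values())
        row = {
            "post_id": rec.post_id,
            "user_id": rec.user_id,
            "date": rec.date,
            "valence": valence,
            "arousal": arousal,
            "n_emotion_tokens": n_tokens,
            "token_counts": dict(counts),
            "quadrant": classify_quadrant(valence, arousal) if n_tokens else None,
        }
        for c in passthrough:
            row[c] = getattr(rec, c)
        rows.append(row)
    return pd.DataFrame(rows)


def emotion_map_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of non-missing posts per circumplex quadrant.

    Missing-score posts are excluded; proportions are over the scored
    posts and sum to 1.  Empty input returns all-zero counts.
    """
    scored = scores.dropna(subset=["valence", "arousal"])
    labels = [
        classify_quadrant(v, a)
        for v, a in zip(scored["valence"], scored["arousal"])
    ]
    counts = pd.Series(labels, dtype=object).value_counts()
    counts = counts.reindex(QUADRANTS, fill_value=0).astype(int)
    total = int(counts.sum())
    props = counts / total if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "proportion": props})


def fit_quadratic(scores: pd.DataFrame | Iterable[float],
                  arousal: Optional[Iterable[float]] = None) -> QuadraticFit:
    """Quadratic OLS regression of arousal on valence.

    Accepts either a scored-post DataFrame (columns valence/arousal;
    missing scores dropped) or two array-likes.  Requires at least 4
    points with at least 3 distinct valence values (otherwise the design
    is rank deficient).  Returns coefficients, R-squared and the overall
    F statistic with (2, n - 3) degrees of freedom.
    """
    if arousal is None:
        frame = scores.dropna(subset=["valence", "arousal"])  # type: ignore[union-attr]
        v = frame["valence"].to_numpy(dtype=float)
        a = frame["arousal"].to_numpy(dtype=float)
    else:
        v = np.asarray(list(scores), dtype=float)
        a = np.asarray(list(arousal), dtype=float)
    n = len(v)
    if n < 4:
        raise ScoringError(f"need at least 4 scored posts, got {n}")
    if len(np.unique(v)) < 3:
        raise ScoringError("need at least 3 distinct valence values")
    X = sm.add_constant(np.column_stack([v, v * v]))
    res = sm.OLS(a, X).fit()
    # a perfect fit makes the F statistic infinite; keep it finite-aware
    f_stat = float(res.fvalue) if np.isfinite(res.fvalue) else math.inf
    f_pvalue = float(res.f_pvalue) if np.isfinite(res.fvalue) else 0.0
    return QuadraticFit(
        intercept=float(res.params[0]),
        linear=float(res.params[1]),
        quadratic=float(res.params[2]),
        r_squared=float(res.rsquared),
        f_stat=f_stat,
        f_pvalue=f_pvalue,
        df=(2, n - 3),
        n=n,
    )
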