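"""Emotion-word frequency and prevalence within a date window.

Counts are over lexicon-matched tokens only (the denominators of the
prevalence figures are "all emotion words found in the posts", not all
segmented words).  Ties in the top-k ranking are broken by code-point
order of the word, for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date
from typing import Optional

import pandas as pd


@dataclass(frozen=True)
class WordFreqTable:
    table: pd.DataFrame  # word, count, prevalence; sorted by count desc
    total_tokens: int
    start: Optional[date]
    end: Optional[date]


def _window_counts(scores: pd.DataFrame, start: Optional[date], end: Optional[date]) -> Counter:
    frame = scores
    if start is not None or end is not None:
        dates = pd.to_datetime(frame["date"]).dt.date
        mask = pd.Series(True, index=frame.index)
        if start is not None:
            mask &= dates >= start
        if end is not None:
            mask &= dates <= end
        frame = frame[mask]
    totals: Counter = Counter()
    for counts in frame["token_counts"]:
        if counts:
            totals.update(counts)
    return totals


def word_frequencies(
    scores: pd.DataFrame,
    start: Optional[date] = None,
    end: Optional[date] = None,
    k: Optional[int] = None,
) -> WordFreqTable:
    """Top-k emotion words by token count in [start, end].

    ``total_tokens`` counts all matched tokens in the window, not just
    the top-k rows, so row prevalences are shares of the full token
    mass.  k=None (or k larger than the vocabulary) returns every word.
    """
    totals = _window_counts(scores, start, end)
    total_tokens = sum(totals.values())
    items = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if k is not None:
        items = items[:k]
    table = pd.DataFrame(items, columns=["word", "count"])
    table["prevalence"] = table["count"] / total_tokens if total_tokens else 0.0
    return WordFreqTable(table=table, total_tokens=total_tokens, start=start, end=end)


def word_prevalence(
    scores: pd.DataFrame,
    word: str,
    start: Optional[date] = None,
    end: Optional[date] = None,
) -> float:
    """Share of one word among all matched emotion tokens in the window."""
    totals = _window_counts(scores, start, end)
    total_tokens = sum(totals.values())
    if total_tokens == 0:
        return 0.0
    return totals.get(word, 0) / total_tokens
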