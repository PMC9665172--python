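"""Valence-arousal lexicon handling.

A lexicon maps words to a pair of affect annotations on the circumplex
plane: *valence*, the pleasantness of the word on a bipolar scale from -4
to +4, and *arousal*, its degree of activation on a unipolar scale from 0
to 8.  The file format is a delimited UTF-8 table with a single header
line and columns ``word``, ``valence``, ``arousal`` (tab-separated by
default, any single-character delimiter accepted).

Emotion words are extracted from text by deterministic forward maximum
matching against the lexicon keys: the text is scanned left to right and
at each position the longest lexicon word starting there is consumed; if
no word starts there the scan advances one character.  This is the
classic dictionary-matching baseline for unsegmented (e.g. Chinese) text
and is fully reproducible, with no statistical segmentation model.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

VALENCE_RANGE = (-4.0, 4.0)
AROUSAL_RANGE = (0.0, 8.0)


class LexiconError(ValueError):
    """Raised for malformed, out-of-range, or duplicated lexicon rows."""


@dataclass(frozen=True)
class LexiconEntry:
    """One emotion word with its valence and arousal annotations."""

    word: str
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        if not self.word:
            raise LexiconError("lexicon word must be a non-empty string")
        if not VALENCE_RANGE[0] <= self.valence <= VALENCE_RANGE[1]:
            raise LexiconError(
                f"valence {self.valence!r} for word {self.word!r} outside "
                f"[{VALENCE_RANGE[0]}, {VALENCE_RANGE[1]}]"
            )
        if not AROUSAL_RANGE[0] <= self.arousal <= AROUSAL_RANGE[1]:
            raise LexiconError(
                f"arousal {self.arousal!r} for word {self.word!r} outside "
                f"[{AROUSAL_RANGE[0]}, {AROUSAL_RANGE[1]}]"
            )


def normalize_text(text: str) -> str:
    """Canonicalize text before dictionary matching.

    Full-width digits and latin letters are mapped to their half-width
    (ASCII) forms and latin letters are lowercased.  No stemming, no
    other folding; the mapping is loss-free for CJK content.
    """
    out = []
    for ch in text:
        o = ord(ch)
        if 0xFF10 <= o <= 0xFF19 or 0xFF21 <= o <= 0xFF3A or 0xFF41 <= o <= 0xFF5A:
            ch = chr(o - 0xFEE0)
        out.append(ch)
    return "".join(out).lower()


class Lexicon:
    """An immutable word -> (valence, arousal) table with exact-match lookup.

    Lookup keys are normalized with :func:`normalize_text`.  Duplicate
    words (after normalization) are a hard error: silently overwriting an
    annotation would corrupt downstream scores.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        for entry in entries:
            key = normalize_text(entry.word)
            if key in self._entries:
                raise LexiconError(f"duplicate lexicon word {entry.word!r}")
            self._entries[key] = LexiconEntry(key, entry.valence, entry.arousal)
        self.max_word_length = max((len(w) for w in self._entries), default=0)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, word: str) -> bool:
        return normalize_text(word) in self._entries

    def __getitem__(self, word: str) -> LexiconEntry:
        return self._entries[normalize_text(word)]

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    @property
    def words(self) -> list[str]:
        return list(self._entries)

    def to_frame(self) -> pd.DataFrame:
        """Return the lexicon as a DataFrame with columns word/valence/arousal."""
        return pd.DataFrame(
            {
                "word": list(self._entries),
                "valence": [e.valence for e in self._entries.values()],
                "arousal": [e.arousal for e in self._entries.values()],
            }
        )


def load_lexicon(path: str | Path, delimiter: str = "\t") -> Lexicon:
    """Load a lexicon from a delimited text file.

    The file must be UTF-8 with one header line and columns ``word``,
    ``valence`` and ``arousal`` (by name, in any order; extra columns are
    ignored).  Rows with non-numeric or out-of-range scores, or duplicate
    words, raise :class:`LexiconError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = {"word", "valence", "arousal"} - set(frame.columns)
    if missing:
        raise LexiconError(
            f"lexicon file {path} is missing columns {sorted(missing)}"
        )
    entries = []
    for row in frame.itertuples(index=True):
        rowno = row.Index + 2  # 1-based, after the header line
        try:
            valence = float(row.valence)
            arousal = float(row.arousal)
        except ValueError as exc:
            raise LexiconError(
                f"{path} row {rowno}: non-numeric score for word {row.word!r}"
            ) from exc
        try:
            entries.append(LexiconEntry(str(row.word), valence, arousal))
        except LexiconError as exc:
            raise LexiconError(f"{path} row {rowno}: {exc}") from exc
    try:
        return Lexicon(entries)
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from exc


def save_lexicon(lexicon: Lexicon, path: str | Path, delimiter: str = "\t") -> None:
    """Write a lexicon to a delimited UTF-8 file (round-trips with load_lexicon)."""
    lexicon.to_frame().to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def match_lexicon_tokens(text: str, lexicon: Lexicon) -> Counter:
    """Count lexicon-word occurrences in text by forward maximum matching.

    Returns a Counter mapping (normalized) lexicon word to its occurrence
    count.  Matched spans never overlap; characters that start no lexicon
    word contribute nothing.  Empty text yields an empty Counter.
    """
    counts: Counter = Counter()
    if not text or len(lexicon) == 0:
        return counts
    s = normalize_text(text)
    entries = lexicon._entries
    maxlen = lexicon.max_word_length
    i, n = 0, len(s)
    while i < n:
        for length in range(min(maxlen, n - i), 0, -1):
            cand = s[i : i + length]
            if cand in entries:
                counts[cand] += 1
                i += length
                break
        else:
            i += 1
    return counts
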