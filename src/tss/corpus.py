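"""Time-stamped message corpora and term-occurrence queries.

A :class:`Corpus` is an ordered (by timestamp) sequence of :class:`Message`
objects with cached term-occurrence indices, so that repeated similarity
queries against the same stream are cheap.  Matching is deliberately simple
and deterministic: case-insensitive token matching, tokens split on
non-alphanumeric boundaries, ``#`` glued to the following token so hashtags
stay distinct from plain words, and multi-word phrases matched as contiguous
ordered token runs.  Any number of occurrences of a term inside one message
counts as a single occurrence of that message.
"""

from __future__ import annotations

import csv
import json
import math
import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Message",
    "Term",
    "TimestampSeries",
    "Corpus",
    "tokenize",
    "matches",
    "load_messages",
    "save_messages",
    "last_n_timestamps",
    "load_term_list",
]

# '#' binds to the following token; everything else splits on non-word chars.
_TOKEN_RE = re.compile(r"#?\w+", re.UNICODE)


def tokenize(text: str) -> tuple[str, ...]:
    """Lower-cased tokens of *text*; hashtags keep their leading ``#``."""
    return tuple(_TOKEN_RE.findall(text.lower()))


@dataclass(frozen=True)
class Message:
    """One time-stamped text unit (a "tweet" in the original setting)."""

    timestamp: float
    text: str
    id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.timestamp):
            raise ValueError(f"message timestamp must be finite, got {self.timestamp!r}")
        if self.text is None:  # empty is fine, None is not
            raise ValueError("message text must not be None")


@dataclass(frozen=True)
class Term:
    """A query term: a single word, a contiguous multi-word phrase, or a hashtag."""

    surface: str
    language: str | None = None

    def __post_init__(self) -> None:
        stripped = self.surface.strip()
        if not stripped:
            raise ValueError("term surface is empty after trimming")
        object.__setattr__(self, "surface", stripped)

    @property
    def tokens(self) -> tuple[str, ...]:
        toks = tokenize(self.surface)
        if not toks:
            raise ValueError(f"term {self.surface!r} contains no matchable token")
        return toks

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.surface


def as_term(term: Term | str) -> Term:
    return term if isinstance(term, Term) else Term(str(term))


@dataclass(frozen=True)
class TimestampSeries:
    """The last-N occurrence times of a term (or term conjunction) at a reference time.

    ``stamps`` are the timestamps tau_i of the up-to-``requested_n`` most recent
    messages containing all of ``terms``, restricted to stamps <= ``reference_time``
    and sorted ascending.
    """

    terms: tuple[Term, ...]
    reference_time: float
    stamps: np.ndarray
    requested_n: int

    def __post_init__(self) -> None:
        stamps = np.asarray(self.stamps, dtype=float)
        object.__setattr__(self, "stamps", stamps)
        if stamps.size and np.any(np.diff(stamps) < 0):
            raise ValueError("stamps must be sorted non-decreasing")
        if stamps.size and stamps[-1] > self.reference_time:
            raise ValueError("stamps must not exceed reference_time")
        if stamps.size > self.requested_n:
            raise ValueError("more stamps than requested_n")

    def __len__(self) -> int:
        return int(self.stamps.size)


def _contains_phrase(tokens: tuple[str, ...], phrase: tuple[str, ...]) -> bool:
    n = len(phrase)
    if n == 1:
        return phrase[0] in tokens
    return any(tokens[i : i + n] == phrase for i in range(len(tokens) - n + 1))


def matches(term: Term | str, message: Message) -> bool:
    """True iff *term* occurs in *message* under the token-matching rule."""
    return _contains_phrase(tokenize(message.text), as_term(term).tokens)


class Corpus(Sequence):
    """An ordered message collection with cached occurrence indices per term."""

    def __init__(self, messages: Iterable[Message], *, sort: bool = True):
        msgs = list(messages)
        if sort:
            msgs.sort(key=lambda m: m.timestamp)  # stable: file order breaks ties
        self._messages: list[Message] = msgs
        self._times = np.array([m.timestamp for m in msgs], dtype=float)
        self._tokens: list[tuple[str, ...]] | None = None
        self._inverted: dict[str, np.ndarray] | None = None
        self._occ_cache: dict[tuple[str, ...], np.ndarray] = {}
        self._pair_cache: dict[tuple, np.ndarray] = {}

    @classmethod
    def coerce(cls, messages: "Corpus | Iterable[Message]") -> "Corpus":
        return messages if isinstance(messages, cls) else cls(messages)

    # -- Sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._messages)

    def __getitem__(self, i):
        return self._messages[i]

    def __iter__(self):
        return iter(self._messages)

    @property
    def times(self) -> np.ndarray:
        """All message timestamps, ascending."""
        return self._times

    # -- occurrence queries ------------------------------------------------
    def _ensure_index(self) -> None:
        if self._inverted is not None:
            return
        self._tokens = [tokenize(m.text) for m in self._messages]
        inverted: dict[str, list[int]] = {}
        for i, toks in enumerate(self._tokens):
            for tok in set(toks):
                inverted.setdefault(tok, []).append(i)
        self._inverted = {tok: np.array(idx, dtype=np.intp) for tok, idx in inverted.items()}

    def occurrence_indices(self, term: Term | str) -> np.ndarray:
        """Ascending message indices containing *term* (once per message)."""
        toks = as_term(term).tokens
        cached = self._occ_cache.get(toks)
        if cached is not None:
            return cached
        self._ensure_index()
        assert self._inverted is not None and self._tokens is not None
        empty = np.array([], dtype=np.intp)
        if len(toks) == 1:
            idx = self._inverted.get(toks[0], empty)
        else:
            candidates = self._inverted.get(toks[0], empty)
            idx = np.array(
                [i for i in candidates if _contains_phrase(self._tokens[i], toks)],
                dtype=np.intp,
            )
        self._occ_cache[toks] = idx
        return idx

    def occurrence_times(self, term: Term | str) -> np.ndarray:
        return self._times[self.occurrence_indices(term)]

    def joint_occurrence_times(self, t1: Term | str, t2: Term | str) -> np.ndarray:
        """Timestamps of messages containing both terms (order inside messages irrelevant)."""
        k1, k2 = as_term(t1).tokens, as_term(t2).tokens
        if k1 == k2:
            return self.occurrence_times(t1)
        key = (min(k1, k2), max(k1, k2))
        cached = self._pair_cache.get(key)
        if cached is None:
            cached = np.intersect1d(
                self.occurrence_indices(t1), self.occurrence_indices(t2), assume_unique=True
            )
            self._pair_cache[key] = cached
        return self._times[cached]


def last_n_timestamps(
    messages: Corpus | Iterable[Message],
    terms: Term | str | Sequence[Term | str],
    reference_time: float,
    n: int,
) -> TimestampSeries:
    """Timestamps of the up-to-``n`` most recent messages (<= reference_time)
    containing all given terms (one term, or a conjunction of two).

    Fewer than ``n`` stamps are returned when fewer matching messages exist;
    an empty series is a valid result, not an error.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if isinstance(terms, (Term, str)):
        term_tuple: tuple[Term, ...] = (as_term(terms),)
    else:
        term_tuple = tuple(as_term(t) for t in terms)
    if not 1 <= len(term_tuple) <= 2:
        raise ValueError("terms must be one Term or a pair of Terms")
    corpus = Corpus.coerce(messages)
    if len(term_tuple) == 1 or term_tuple[0].tokens == term_tuple[1].tokens:
        times = corpus.occurrence_times(term_tuple[0])
    else:
        times = corpus.joint_occurrence_times(term_tuple[0], term_tuple[1])
    hi = int(np.searchsorted(times, reference_time, side="right"))
    stamps = times[max(0, hi - n) : hi]
    return TimestampSeries(
        terms=term_tuple, reference_time=reference_time, stamps=stamps, requested_n=n
    )


# -- file formats ---------------------------------------------------------
#
# JSONL: one object per line, keys "t" (epoch seconds), "text", optional "id".
# CSV: header t,text[,id], RFC-4180 quoting.


def _coerce_timestamp(raw, where: str) -> float:
    try:
        t = float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"{where}: unparseable timestamp {raw!r}") from None
    if not math.isfinite(t):
        raise ValueError(f"{where}: non-finite timestamp {raw!r}")
    return t


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"unknown corpus format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".json", ".ndjson"):
        return "jsonl"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer corpus format from {path.name!r}; pass format=")


def load_messages(path, format: str | None = None) -> Corpus:
    """Read a JSONL or CSV corpus; messages are returned sorted ascending by
    timestamp with file order breaking ties. Malformed records raise with the
    offending line number."""
    path = Path(path)
    fmt = _infer_format(path, format)
    messages: list[Message] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: malformed JSON record: {exc}") from None
                if not isinstance(rec, dict):
                    raise ValueError(f"line {lineno}: record is not an object")
                if "text" not in rec:
                    raise ValueError(f"line {lineno}: record missing 'text' field")
                if "t" not in rec:
                    raise ValueError(f"line {lineno}: record missing 't' field")
                if not isinstance(rec["text"], str):
                    raise ValueError(f"line {lineno}: 'text' is not a string")
                t = _coerce_timestamp(rec["t"], f"line {lineno}")
                messages.append(Message(timestamp=t, text=rec["text"], id=str(rec.get("id", ""))))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"t", "text"} <= set(reader.fieldnames):
                raise ValueError(f"{path.name}: CSV header must contain 't' and 'text'")
            for rownum, row in enumerate(reader, start=2):  # header is line 1
                if row.get("text") is None:
                    raise ValueError(f"line {rownum}: record missing 'text' field")
                t = _coerce_timestamp(row.get("t"), f"line {rownum}")
                messages.append(Message(timestamp=t, text=row["text"], id=row.get("id") or ""))
    return Corpus(messages)


def save_messages(messages: Iterable[Message], path, format: str | None = None) -> None:
    """Write messages in the JSONL or CSV dialect read by :func:`load_messages`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for m in messages:
                fh.write(json.dumps({"t": m.timestamp, "text": m.text, "id": m.id}) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "text", "id"])
            for m in messages:
                writer.writerow([repr(m.timestamp), m.text, m.id])


def load_term_list(path) -> list[Term]:
    """One term per line; a leading '#' is a literal hashtag, not a comment."""
    terms: list[Term] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            surface = line.strip()
            if surface:
                terms.append(Term(surface))
    return terms
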