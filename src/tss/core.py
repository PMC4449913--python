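"""The velocity-based similarity measure.

The production rate ("velocity") of a term ``w`` at time ``t`` is estimated
from the time-stamp series of the last ``N`` messages containing ``w``::

    Phi(w) = [ mean inter-arrival time of the last N occurrences ]^{-1}
           = (M - 1) / (tau_M - tau_1)          (the interval sum telescopes)

with ``M <= N`` the stamps actually available.  The similarity between two
terms is the co-occurrence rate normalized by the faster of the two terms,
compressed by a scaling exponent ``alpha``::

    TSS(w1, w2) = ( Phi(w1 ^ w2) / max(Phi(w1), Phi(w2)) )^alpha

Defaults follow the original measure: N = 30, alpha = 1/4.  Whenever any
needed rate is undefined (fewer than two stamps, or zero span), the
similarity is defined to be 0; with finite windows the estimated ratio can
exceed one, and is clipped so TSS stays in [0, 1].
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, Message, Term, TimestampSeries, as_term, last_n_timestamps

__all__ = [
    "QueryConfig",
    "RateEstimate",
    "TSSMatrix",
    "DEFAULT_CONFIG",
    "estimate_rate",
    "tss",
    "tss_matrix",
    "tss_series",
    "baseline_joint_frequency",
]


@dataclass(frozen=True)
class QueryConfig:
    """Window size ``n`` (number of most recent occurrences used by the rate
    estimator) and scaling exponent ``alpha``."""

    n: int = 30
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    @classmethod
    def from_mapping(cls, mapping) -> "QueryConfig":
        known = {k: mapping[k] for k in ("n", "alpha") if k in mapping}
        if "n" in known:
            known["n"] = int(known["n"])
        if "alpha" in known:
            known["alpha"] = float(known["alpha"])
        return cls(**known)

    @classmethod
    def from_file(cls, path) -> "QueryConfig":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"{path.name}: config must be a mapping")
        return cls.from_mapping(data)


DEFAULT_CONFIG = QueryConfig()


@dataclass(frozen=True)
class RateEstimate:
    """Occurrence rate in events per second; ``value`` is None when undefined
    (fewer than two stamps, or all stamps coincident)."""

    value: float | None
    n_used: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def estimate_rate(series: TimestampSeries) -> RateEstimate:
    """Inverse mean inter-arrival time of the series.

    The mean of consecutive differences telescopes, so the estimate depends on
    the stamps only through (first, last, count): (M-1) / (tau_M - tau_1).
    """
    stamps = np.asarray(series.stamps, dtype=float)
    m = int(stamps.size)
    if m < 2:
        return RateEstimate(value=None, n_used=m)
    span = float(stamps[-1] - stamps[0])
    if span <= 0.0:
        return RateEstimate(value=None, n_used=m)
    return RateEstimate(value=(m - 1) / span, n_used=m)


def _rate_at(corpus: Corpus, terms, reference_time: float, n: int) -> RateEstimate:
    return estimate_rate(last_n_timestamps(corpus, terms, reference_time, n))


def tss(
    messages: Corpus | Iterable[Message],
    w1: Term | str,
    w2: Term | str,
    reference_time: float,
    config: QueryConfig = DEFAULT_CONFIG,
) -> float:
    """Similarity of ``w1`` and ``w2`` at ``reference_time``, in [0, 1].

    Symmetric in its term arguments; 0 whenever either term or the pair lacks
    a defined rate; 1 for a term paired with itself when its rate is defined.
    """
    corpus = Corpus.coerce(messages)
    w1, w2 = as_term(w1), as_term(w2)
    r1 = _rate_at(corpus, w1, reference_time, config.n)
    if w1.tokens == w2.tokens:
        return 1.0 if r1.defined else 0.0
    r2 = _rate_at(corpus, w2, reference_time, config.n)
    rj = _rate_at(corpus, (w1, w2), reference_time, config.n)
    if not (r1.defined and r2.defined and rj.defined):
        return 0.0
    ratio = min(1.0, rj.value / max(r1.value, r2.value))
    return float(ratio**config.alpha)


def baseline_joint_frequency(
    messages: Corpus | Iterable[Message],
    w1: Term | str,
    w2: Term | str,
    reference_time: float,
    config: QueryConfig = DEFAULT_CONFIG,
) -> float:
    """Raw co-occurrence rate Phi(w1 ^ w2) in occurrences/second (0 when
    undefined) — the unnormalized baseline the measure is compared against."""
    w1, w2 = as_term(w1), as_term(w2)
    corpus = Corpus.coerce(messages)
    terms = w1 if w1.tokens == w2.tokens else (w1, w2)
    r = _rate_at(corpus, terms, reference_time, config.n)
    return float(r.value) if r.defined else 0.0


@dataclass(frozen=True)
class TSSMatrix:
    """Symmetric term-by-term similarity matrix at one reference time."""

    vocabulary: tuple[Term, ...]
    time: float
    values: np.ndarray
    config: QueryConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        vocab = tuple(as_term(t) for t in self.vocabulary)
        object.__setattr__(self, "vocabulary", vocab)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        v = len(vocab)
        if values.shape != (v, v):
            raise ValueError(f"values shape {values.shape} does not match vocabulary size {v}")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.vocabulary]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.surfaces, columns=self.surfaces)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format ``term1,term2,time,tss`` over unordered pairs (i < j)."""
        surfaces = self.surfaces
        rows = [
            (surfaces[i], surfaces[j], self.time, self.values[i, j])
            for i in range(len(surfaces))
            for j in range(i + 1, len(surfaces))
        ]
        return pd.DataFrame(rows, columns=["term1", "term2", "time", "tss"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="term")

    @classmethod
    def from_csv(cls, path, time: float = 0.0, config: QueryConfig = DEFAULT_CONFIG) -> "TSSMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix CSV row and column terms differ")
        return cls(
            vocabulary=tuple(Term(str(t)) for t in df.index),
            time=time,
            values=df.to_numpy(dtype=float),
            config=config,
        )


def tss_matrix(
    messages: Corpus | Iterable[Message],
    vocabulary: Sequence[Term | str],
    reference_time: float,
    config: QueryConfig = DEFAULT_CONFIG,
) -> TSSMatrix:
    """Pairwise similarity over a vocabulary; each unordered pair computed once.

    Diagonal entries are 1 for terms with a defined rate at ``reference_time``
    and 0 otherwise.
    """
    vocab = tuple(as_term(t) for t in vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    token_keys = [t.tokens for t in vocab]
    if len(set(token_keys)) != len(token_keys):
        dupes = sorted({t.surface for t, k in zip(vocab, token_keys) if token_keys.count(k) > 1})
        raise ValueError(f"vocabulary contains duplicate terms: {dupes}")
    corpus = Corpus.coerce(messages)
    v = len(vocab)
    rates = [_rate_at(corpus, t, reference_time, config.n) for t in vocab]
    values = np.zeros((v, v), dtype=float)
    for i in range(v):
        values[i, i] = 1.0 if rates[i].defined else 0.0
        for j in range(i + 1, v):
            if not (rates[i].defined and rates[j].defined):
                continue
            rj = _rate_at(corpus, (vocab[i], vocab[j]), reference_time, config.n)
            if not rj.defined:
                continue
            ratio = min(1.0, rj.value / max(rates[i].value, rates[j].value))
            values[i, j] = values[j, i] = ratio**config.alpha
    return TSSMatrix(vocabulary=vocab, time=reference_time, values=values, config=config)


def tss_series(
    messages: Corpus | Iterable[Message],
    vocabulary: Sequence[Term | str],
    times: Sequence[float],
    config: QueryConfig = DEFAULT_CONFIG,
) -> list[TSSMatrix]:
    """One similarity matrix per reference time (times must be ascending).

    Each matrix is computed independently from the stamps at or before its own
    reference time; there is no look-ahead and no state carried across times.
    """
    times = list(times)
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be ascending")
    corpus = Corpus.coerce(messages)  # shared occurrence cache across time points
    return [tss_matrix(corpus, vocabulary, t, config) for t in times]
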