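"""Synthetic microblog streams with analytic rate and similarity oracles.

Messages arrive as a Poisson process; each message independently draws one
topic from a weighted mixture and then includes each vocabulary word with
that topic's per-word inclusion probability.  This topic-mixture construction
gives closed-form occurrence and co-occurrence rates for every word pair

    rate(w)        = Lambda * sum_k  weight_k * p_k(w)
    joint(w1, w2)  = Lambda * sum_k  weight_k * p_k(w1) * p_k(w2)

and therefore an analytic value of the similarity measure for recovery
testing, while naturally producing category clusters (words sharing a topic
co-occur often; words in disjoint topics never do).  Piecewise-constant
parameter schedules emulate external events: a segment boundary switches the
generative model, and the estimator's sliding last-N window then produces the
gradual responses seen in real event-driven streams.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corpus import Corpus, Message, Term, as_term

__all__ = [
    "Topic",
    "StreamModel",
    "Segment",
    "EventSchedule",
    "simulate_stream",
    "true_rate",
    "true_joint_rate",
    "true_tss",
    "category_model",
    "draw_schedule",
    "crisis_schedule",
    "load_schedule",
    "schedule_from_dict",
    "true_tss_table",
]


@dataclass(frozen=True)
class Topic:
    weight: float
    inclusion: Mapping[str, float]  # word -> per-message inclusion probability

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"topic weight must be >= 0, got {self.weight}")
        for w, p in self.inclusion.items():
            if not 0 <= p <= 1:
                raise ValueError(f"inclusion probability for {w!r} must be in [0,1], got {p}")

    def p(self, word: str) -> float:
        return float(self.inclusion.get(word, 0.0))


@dataclass(frozen=True)
class StreamModel:
    """Generative parameters for one stationary stretch of the stream."""

    message_rate: float  # Lambda, messages per second
    topics: tuple[Topic, ...]
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "topics", tuple(self.topics))
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        if self.message_rate <= 0:
            raise ValueError(f"message_rate must be > 0, got {self.message_rate}")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary contains duplicates")
        if not self.topics:
            raise ValueError("at least one topic is required")
        total = sum(t.weight for t in self.topics)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"topic weights must sum to 1, got {total}")
        vocab = set(self.vocabulary)
        for t in self.topics:
            unknown = set(t.inclusion) - vocab
            if unknown:
                raise ValueError(f"topic mentions words outside the vocabulary: {sorted(unknown)}")


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    model: StreamModel

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"segment must have end > start, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class EventSchedule:
    """Contiguous, non-overlapping half-open segments [start, end)."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.end, b.start, atol=1e-9):
                raise ValueError(
                    f"segments must be contiguous: [{a.start},{a.end}) then [{b.start},{b.end})"
                )

    @classmethod
    def stationary(cls, model: StreamModel, duration: float, start: float = 0.0) -> "EventSchedule":
        return cls(segments=(Segment(start=start, end=start + duration, model=model),))

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def model_at(self, time: float) -> StreamModel:
        for seg in self.segments:
            if seg.start <= time < seg.end:
                return seg.model
        raise ValueError(f"time {time} outside schedule [{self.start}, {self.end})")


def simulate_stream(schedule: EventSchedule | StreamModel, seed, duration: float | None = None) -> Corpus:
    """Draw a message stream from a schedule (or a stationary model + duration).

    Arrivals within each segment are a homogeneous Poisson process at the
    segment's message rate; message text is the space-join of the included
    words in vocabulary order.  Identical seeds give byte-identical corpora.
    """
    if isinstance(schedule, StreamModel):
        if duration is None:
            raise ValueError("duration is required when passing a bare StreamModel")
        schedule = EventSchedule.stationary(schedule, duration)
    rng = np.random.default_rng(seed)
    messages: list[Message] = []
    counter = 0
    for seg in schedule.segments:
        model = seg.model
        vocab = model.vocabulary
        n = int(rng.poisson(model.message_rate * (seg.end - seg.start)))
        times = np.sort(rng.uniform(seg.start, seg.end, size=n))
        weights = np.array([t.weight for t in model.topics], dtype=float)
        weights = weights / weights.sum()
        topic_idx = rng.choice(len(model.topics), size=n, p=weights)
        probs = np.array([[t.p(w) for w in vocab] for t in model.topics], dtype=float)
        include = rng.random((n, len(vocab))) < probs[topic_idx]
        for k in range(n):
            words = [vocab[j] for j in np.flatnonzero(include[k])]
            messages.append(Message(timestamp=float(times[k]), text=" ".join(words), id=f"m{counter:08d}"))
            counter += 1
    return Corpus(messages, sort=False)  # segment-wise sorted and contiguous


# -- analytic oracles ------------------------------------------------------


def true_rate(model: StreamModel, w: Term | str) -> float:
    """Expected rate (messages/second) of messages containing *w*."""
    word = as_term(w).surface
    return float(model.message_rate * sum(t.weight * t.p(word) for t in model.topics))


def true_joint_rate(model: StreamModel, w1: Term | str, w2: Term | str) -> float:
    """Expected rate of messages containing both words (inclusion is
    conditionally independent given the topic)."""
    a, b = as_term(w1).surface, as_term(w2).surface
    if a == b:
        return true_rate(model, w1)
    return float(model.message_rate * sum(t.weight * t.p(a) * t.p(b) for t in model.topics))


def true_tss(model: StreamModel, w1: Term | str, w2: Term | str, alpha: float = 0.25) -> float:
    """The similarity implied by the model's exact rates; 0 when either word
    never occurs."""
    r1, r2 = true_rate(model, w1), true_rate(model, w2)
    if r1 <= 0 or r2 <= 0:
        return 0.0
    if as_term(w1).surface == as_term(w2).surface:
        return 1.0
    joint = true_joint_rate(model, w1, w2)
    if joint <= 0:
        return 0.0
    return float(min(1.0, joint / max(r1, r2)) ** alpha)


def true_tss_table(model: StreamModel, alpha: float = 0.25, segment: int | str = 0) -> pd.DataFrame:
    """Ground-truth ``term1,term2,segment,true_tss`` table over all unordered pairs."""
    vocab = model.vocabulary
    rows = [
        (vocab[i], vocab[j], segment, true_tss(model, vocab[i], vocab[j], alpha=alpha))
        for i in range(len(vocab))
        for j in range(i + 1, len(vocab))
    ]
    return pd.DataFrame(rows, columns=["term1", "term2", "segment", "true_tss"])


def category_model(
    categories: Mapping[str, Sequence[str]],
    message_rate: float = 2.0,
    inclusion: float = 0.5,
    background: float = 0.0,
    weights: Mapping[str, float] | None = None,
) -> StreamModel:
    """One topic per semantic category: a topic includes its own words with
    probability ``inclusion`` and every other word with ``background``.

    Equal topic weights by default.  With background 0, words from different
    categories never co-occur and their true similarity is exactly 0.
    """
    labels = list(categories)
    if not labels:
        raise ValueError("at least one category is required")
    vocab: list[str] = []
    for words in categories.values():  # dedupe: a word may sit in several categories
        for w in words:
            if w not in vocab:
                vocab.append(w)
    if weights is None:
        weights = {lab: 1.0 / len(labels) for lab in labels}
    topics = tuple(
        Topic(
            weight=float(weights[lab]),
            inclusion={w: (inclusion if w in set(categories[lab]) else background) for w in vocab},
        )
        for lab in labels
    )
    return StreamModel(message_rate=message_rate, topics=topics, vocabulary=tuple(vocab))


# -- canonical event scenarios ---------------------------------------------


def draw_schedule(
    n_groups: int = 8,
    group_size: int = 4,
    message_rate: float = 2.0,
    background: float = 0.15,
    group_inclusion: float = 0.8,
    group_topic_weight: float = 0.1,
    pre: float = 2000.0,
    event: float = 300.0,
    post: float = 2700.0,
) -> tuple[EventSchedule, dict[str, str]]:
    """A tournament-draw scenario: exchangeable items suddenly co-occur by group.

    Before and after the event every item appears independently at a common
    background probability, so all pairs are statistically interchangeable.
    During the event window each group gets its own topic that co-includes its
    members, imprinting the partition on the co-occurrence structure.  Returns
    the schedule and the item -> group assignment.
    """
    items = [f"team{i:02d}" for i in range(n_groups * group_size)]
    groups = {item: f"g{i // group_size}" for i, item in enumerate(items)}
    baseline_model = StreamModel(
        message_rate=message_rate,
        topics=(Topic(1.0, {w: background for w in items}),),
        vocabulary=tuple(items),
    )
    w_bg = 1.0 - n_groups * group_topic_weight
    if w_bg <= 0:
        raise ValueError("group_topic_weight too large for the number of groups")
    event_topics = [Topic(w_bg, {w: background for w in items})]
    for g in range(n_groups):
        members = items[g * group_size : (g + 1) * group_size]
        event_topics.append(Topic(group_topic_weight, {w: group_inclusion for w in members}))
    event_model = StreamModel(
        message_rate=message_rate, topics=tuple(event_topics), vocabulary=tuple(items)
    )
    schedule = EventSchedule(
        segments=(
            Segment(0.0, pre, baseline_model),
            Segment(pre, pre + event, event_model),
            Segment(pre + event, pre + event + post, baseline_model),
        )
    )
    return schedule, groups


def crisis_schedule(
    concept: str = "light",
    g1: Sequence[str] = ("luminosity", "candle", "spark", "bulb", "creativity"),
    g2: Sequence[str] = ("conflict", "tension", "riot", "protest", "blackout"),
    message_rate: float = 2.0,
    inclusion: float = 0.3,
    baseline: float = 0.02,
    pre: float = 3000.0,
    event: float = 1500.0,
    post: float = 3500.0,
) -> EventSchedule:
    """A concept-drift scenario: a concept's co-occurrence moves between anchor sets.

    Two equal-weight topics carry the concept's usual neighborhood (g1) and a
    crisis neighborhood (g2).  Normally the concept appears in the g1 topic at
    ``inclusion`` and in the g2 topic only at a small ``baseline``; during the
    event window it also joins the g2 topic at ``inclusion``, pulling its mean
    similarity toward the crisis words, then reverts.
    """
    vocab = (concept, *g1, *g2)
    if len(set(vocab)) != len(vocab):
        raise ValueError("concept and anchor groups must be distinct words")

    def model(concept_in_g2: float) -> StreamModel:
        topic_g1 = Topic(0.5, {concept: inclusion, **{w: inclusion for w in g1}})
        topic_g2 = Topic(0.5, {concept: concept_in_g2, **{w: inclusion for w in g2}})
        return StreamModel(message_rate=message_rate, topics=(topic_g1, topic_g2), vocabulary=vocab)

    return EventSchedule(
        segments=(
            Segment(0.0, pre, model(baseline)),
            Segment(pre, pre + event, model(inclusion)),
            Segment(pre + event, pre + event + post, model(baseline)),
        )
    )


# -- config files ----------------------------------------------------------


def schedule_from_dict(cfg: Mapping) -> EventSchedule:
    """Build a schedule from a plain mapping (parsed YAML/JSON).

    Expected shape::

        vocabulary: [w1, w2, ...]
        segments:
          - {start: 0, end: 1000, message_rate: 2.0,
             topics: [{weight: 1.0, inclusion: {w1: 0.2, w2: 0.1}}]}
    """
    try:
        vocab = tuple(str(w) for w in cfg["vocabulary"])
        seg_cfgs = cfg["segments"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"schedule config missing required key: {exc}") from None
    segments = []
    for i, sc in enumerate(seg_cfgs):
        try:
            topics = tuple(
                Topic(weight=float(t["weight"]), inclusion={str(w): float(p) for w, p in t["inclusion"].items()})
                for t in sc["topics"]
            )
            model = StreamModel(
                message_rate=float(sc["message_rate"]), topics=topics, vocabulary=vocab
            )
            segments.append(Segment(start=float(sc["start"]), end=float(sc["end"]), model=model))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"segment {i}: malformed config ({exc})") from None
    return EventSchedule(segments=tuple(segments))


def load_schedule(path) -> EventSchedule:
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{Path(path).name}: schedule config must be a mapping")
    return schedule_from_dict(cfg)
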