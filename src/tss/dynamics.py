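"""Time-resolved analyses of the similarity network.

Three instruments for event-driven reorganization:

* **group-organization performance** — for each item in a partitioned
  vocabulary (e.g. 32 national teams in 8 tournament groups of 4), take the
  three most-similar other items and score 1, 2/3, 1/3 or 0 according to how
  many of them are groupmates; the vocabulary mean tracks how strongly the
  similarity structure encodes the grouping.  With no structure the expected
  per-item score is 3/31 for 32 items in groups of 4.
* **anchor drift** — a concept's mean similarity to two fixed anchor word
  sets over time, quantifying semantic drift between neighborhoods.
* **matrix-norm series** — the off-diagonal Frobenius norm of the similarity
  matrix at each time, a scalar summary of overall network activation, with a
  Pearson correlation helper for comparing subnetworks over a time window.
"""

from __future__ import annotations

import csv
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .core import DEFAULT_CONFIG, QueryConfig, TSSMatrix, tss, tss_series
from .corpus import Corpus, Message, Term, as_term
from .evaluation import classical_mds, tss_to_dissimilarity

__all__ = [
    "GroupAssignment",
    "GroupPerformance",
    "group_performance",
    "anchor_drift",
    "concept_trajectory",
    "matrix_norm",
    "matrix_norm_series",
    "subnetwork_correlation",
]


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping from item term to group label (every item in exactly one group)."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        normalized = {as_term(k).surface.lower(): str(v) for k, v in self.groups.items()}
        if len(normalized) != len(self.groups):
            raise ValueError("duplicate items in group assignment")
        object.__setattr__(self, "groups", normalized)

    @classmethod
    def from_csv(cls, path) -> "GroupAssignment":
        """Read an ``item,group`` CSV."""
        mapping: dict[str, str] = {}
        with Path(path).open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"item", "group"} <= set(reader.fieldnames):
                raise ValueError("group CSV header must be item,group")
            for rownum, row in enumerate(reader, start=2):
                item = (row.get("item") or "").strip()
                group = (row.get("group") or "").strip()
                if not item or not group:
                    raise ValueError(f"row {rownum}: empty item or group")
                if item.lower() in mapping:
                    raise ValueError(f"row {rownum}: duplicate item {item!r}")
                mapping[item.lower()] = group
        return cls(groups=mapping)

    def group_of(self, item: Term | str) -> str:
        key = as_term(item).surface.lower()
        if key not in self.groups:
            raise ValueError(f"item {as_term(item).surface!r} has no group assignment")
        return self.groups[key]

    def sizes(self) -> Counter:
        return Counter(self.groups.values())


@dataclass(frozen=True)
class GroupPerformance:
    """Per-item top-3 groupmate scores (values in {0, 1/3, 2/3, 1}) and their mean."""

    scores: pd.Series
    mean: float
    time: float


def group_performance(matrix: TSSMatrix, groups: GroupAssignment) -> GroupPerformance:
    """Score how well the similarity matrix encodes the group partition.

    For every item, the 3 largest off-diagonal similarities are selected (ties
    broken by vocabulary order) and the score is the fraction of them that are
    groupmates.  Requires every item to be assigned, each group to have at
    least 4 members, and at least 4 items overall.
    """
    surfaces = matrix.surfaces
    v = len(surfaces)
    if v < 4:
        raise ValueError(f"need at least 4 items to pick top-3 neighbors, got {v}")
    labels = [groups.group_of(s) for s in surfaces]
    sizes = Counter(labels)
    small = {g: c for g, c in sizes.items() if c < 4}
    if small:
        raise ValueError(f"every group needs >= 4 members (item + 3 groupmates); too small: {small}")
    _, codes = np.unique(labels, return_inverse=True)
    values = matrix.values.copy()
    np.fill_diagonal(values, -np.inf)  # exclude self; stable sort keeps vocab order on ties
    order = np.argsort(-values, axis=1, kind="stable")
    top3 = order[:, :3]
    same = codes[top3] == codes[:, None]
    scores = same.sum(axis=1) / 3.0
    series = pd.Series(scores, index=surfaces, name="score")
    return GroupPerformance(scores=series, mean=float(scores.mean()), time=matrix.time)


def anchor_drift(
    messages: Corpus | Iterable[Message],
    concept: Term | str,
    group1: Sequence[Term | str],
    group2: Sequence[Term | str],
    times: Sequence[float],
    config: QueryConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Mean similarity of *concept* to each anchor group at every time point.

    Returns a frame with columns ``time, mean_tss_g1, mean_tss_g2``.  The two
    anchor groups must be non-empty and disjoint, and must not contain the
    concept itself.
    """
    concept = as_term(concept)
    g1 = [as_term(t) for t in group1]
    g2 = [as_term(t) for t in group2]
    if not g1 or not g2:
        raise ValueError("anchor groups must be non-empty")
    k1 = {t.tokens for t in g1}
    k2 = {t.tokens for t in g2}
    overlap = k1 & k2
    if overlap:
        raise ValueError(f"anchor groups overlap: {sorted(' '.join(k) for k in overlap)}")
    if concept.tokens in k1 | k2:
        raise ValueError(f"concept {concept.surface!r} must not belong to an anchor group")
    corpus = Corpus.coerce(messages)
    rows = []
    for t in times:
        m1 = float(np.mean([tss(corpus, concept, x, t, config) for x in g1]))
        m2 = float(np.mean([tss(corpus, concept, x, t, config) for x in g2]))
        rows.append((t, m1, m2))
    return pd.DataFrame(rows, columns=["time", "mean_tss_g1", "mean_tss_g2"])


def concept_trajectory(
    messages: Corpus | Iterable[Message],
    concept: Term | str,
    anchors: Sequence[Term | str],
    times: Sequence[float],
    config: QueryConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D trajectory of a concept through a fixed anchor embedding.

    The anchors are embedded once by classical MDS of the time-averaged
    (1 - similarity) dissimilarities; at each time the concept is placed at
    the point minimizing the squared mismatch between its embedded distances
    to the anchors and its observed dissimilarities.  Returns
    ``(trajectory, anchor_coords)`` frames with columns ``time,x,y`` and
    ``term,x,y``.
    """
    concept = as_term(concept)
    anchors = [as_term(t) for t in anchors]
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchors for a 2-D embedding")
    corpus = Corpus.coerce(messages)
    mats = tss_series(corpus, anchors, list(times), config)
    avg = np.mean([m.values for m in mats], axis=0)
    avg = (avg + avg.T) / 2.0
    coords = classical_mds(tss_to_dissimilarity(avg), dims=2)
    positions = []
    for t, mat in zip(times, mats):
        d = np.array([1.0 - tss(corpus, concept, a, t, config) for a in anchors])

        def loss(x, d=d):
            dist = np.linalg.norm(coords - x, axis=1)
            return float(np.sum((dist - d) ** 2))

        res = minimize(loss, x0=coords.mean(axis=0), method="Nelder-Mead")
        positions.append((t, float(res.x[0]), float(res.x[1])))
    traj = pd.DataFrame(positions, columns=["time", "x", "y"])
    anchor_coords = pd.DataFrame(
        {"term": [a.surface for a in anchors], "x": coords[:, 0], "y": coords[:, 1]}
    )
    return traj, anchor_coords


def matrix_norm(matrix: TSSMatrix) -> float:
    """Frobenius norm of the similarity matrix with the diagonal excluded
    (self-similarity is constant and carries no signal)."""
    values = matrix.values.copy()
    np.fill_diagonal(values, 0.0)
    return float(np.linalg.norm(values))


def matrix_norm_series(series: Sequence[TSSMatrix]) -> pd.DataFrame:
    """Off-diagonal Frobenius norm at every time point; all matrices must
    share a vocabulary."""
    if not series:
        raise ValueError("empty matrix series")
    first = series[0].surfaces
    for m in series[1:]:
        if m.surfaces != first:
            raise ValueError("matrices in a norm series must share the same vocabulary")
    return pd.DataFrame(
        [(m.time, matrix_norm(m)) for m in series], columns=["time", "norm"]
    )


def _norm_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        if not {"time", "norm"} <= set(obj.columns):
            raise ValueError("norm series frame must have 'time' and 'norm' columns")
        return obj[["time", "norm"]]
    times, norms = obj
    return pd.DataFrame({"time": np.asarray(times, float), "norm": np.asarray(norms, float)})


def subnetwork_correlation(
    norms_a, norms_b, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Pearson correlation (and p-value) of two norm series on their shared
    time grid, optionally restricted to a closed time window."""
    a, b = _norm_frame(norms_a), _norm_frame(norms_b)
    merged = a.merge(b, on="time", suffixes=("_a", "_b"))
    if window is not None:
        lo, hi = window
        merged = merged[(merged["time"] >= lo) & (merged["time"] <= hi)]
    if len(merged) < 3:
        raise ValueError(f"need at least 3 aligned time points, got {len(merged)}")
    r, p = pearsonr(merged["norm_a"], merged["norm_b"])
    return float(r), float(p)
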