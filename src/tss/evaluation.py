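"""Validation harnesses: synonym ranking, cross-validated category
classification of similarity rows, and classical multidimensional scaling."""

from __future__ import annotations

import csv
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .core import TSSMatrix

__all__ = [
    "SynonymTestItem",
    "synonym_rank",
    "load_synonym_items",
    "synonym_test",
    "CrossvalResult",
    "crossval_classify",
    "classical_mds",
    "tss_to_dissimilarity",
]


# -- synonym-rank test -----------------------------------------------------


@dataclass(frozen=True)
class SynonymTestItem:
    """A probe word, its candidate list, and which candidate is the synonym."""

    probe: str
    candidates: tuple[str, ...]
    synonym_index: int

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValueError(f"probe {self.probe!r}: need at least 2 candidates")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError(f"probe {self.probe!r}: candidates must be distinct")
        if not 0 <= self.synonym_index < len(self.candidates):
            raise ValueError(f"probe {self.probe!r}: synonym index out of range")


def synonym_rank(scores: Sequence[float], synonym_index: int) -> float:
    """Normalized ascending-rank position of the synonym among the candidates.

    Scores are sorted increasing; position = (rank - 1) / (M - 1), so 1.0
    means the synonym is the most similar candidate and 0.0 the least.  Tied
    scores receive the mean of their ranks.  The statistic depends on scores
    only through their ordering, so it is invariant under strictly monotone
    transforms.
    """
    scores = np.asarray(scores, dtype=float)
    m = scores.size
    if m < 2:
        raise ValueError("need at least 2 candidates")
    if not 0 <= synonym_index < m:
        raise ValueError(f"synonym index {synonym_index} out of range for {m} candidates")
    ranks = rankdata(scores, method="average")
    return float((ranks[synonym_index] - 1.0) / (m - 1.0))


def load_synonym_items(path) -> list[SynonymTestItem]:
    """Read ``probe,candidate,is_synonym`` CSV; each probe needs exactly one
    candidate flagged as the synonym."""
    by_probe: dict[str, list[tuple[str, bool]]] = {}
    order: list[str] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"probe", "candidate", "is_synonym"} <= set(reader.fieldnames):
            raise ValueError("synonym CSV header must be probe,candidate,is_synonym")
        for rownum, row in enumerate(reader, start=2):
            probe, cand = row["probe"].strip(), row["candidate"].strip()
            if not probe or not cand:
                raise ValueError(f"row {rownum}: empty probe or candidate")
            flag = str(row["is_synonym"]).strip().lower() in ("1", "true", "yes")
            if probe not in by_probe:
                by_probe[probe] = []
                order.append(probe)
            by_probe[probe].append((cand, flag))
    items = []
    for probe in order:
        cands = by_probe[probe]
        syn = [i for i, (_, flag) in enumerate(cands) if flag]
        if len(syn) != 1:
            raise ValueError(f"probe {probe!r}: expected exactly one synonym, got {len(syn)}")
        items.append(
            SynonymTestItem(
                probe=probe, candidates=tuple(c for c, _ in cands), synonym_index=syn[0]
            )
        )
    return items


def synonym_test(score_fn, items: Sequence[SynonymTestItem]) -> pd.DataFrame:
    """Apply :func:`synonym_rank` to every item; ``score_fn(probe, candidate)``
    supplies the similarity values (e.g. a closure over ``tss``)."""
    rows = [
        (it.probe, synonym_rank([score_fn(it.probe, c) for c in it.candidates], it.synonym_index))
        for it in items
    ]
    return pd.DataFrame(rows, columns=["probe", "position"])


# -- cross-validated classification ---------------------------------------


@dataclass(frozen=True)
class CrossvalResult:
    fold_accuracies: np.ndarray
    mean: float
    classifier: str
    k: int


def _make_classifier(name: str, train_size: int, knn_neighbors: int):
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=min(knn_neighbors, train_size))
    raise ValueError(f"unknown classifier {name!r}; use 'gaussian_nb' or 'knn'")


def crossval_classify(
    data: TSSMatrix | np.ndarray,
    labels: Sequence | Mapping[str, str] | None = None,
    k: int = 10,
    classifier: str = "gaussian_nb",
    seed: int = 0,
    knn_neighbors: int = 1,
) -> CrossvalResult:
    """Mean held-out accuracy of classifying items into their categories from
    their similarity rows.

    Each item's feature vector is its row of the similarity matrix restricted
    to the columns of the current training fold, so a held-out item never sees
    its own self-similarity.  Folds are stratified by class when every class
    has at least ``k`` members (otherwise plain shuffled folds are used) and
    are drawn reproducibly from ``seed``.
    """
    if isinstance(data, TSSMatrix):
        X = np.asarray(data.values, dtype=float)
        if labels is None:
            raise ValueError("labels are required")
        if isinstance(labels, Mapping):
            lab_map = {str(k_).lower(): v for k_, v in labels.items()}
            y_raw = []
            for t in data.surfaces:
                if t.lower() not in lab_map:
                    raise ValueError(f"item {t!r} has no label")
                y_raw.append(lab_map[t.lower()])
        else:
            y_raw = list(labels)
    else:
        X = np.asarray(data, dtype=float)
        y_raw = list(labels) if labels is not None else None
        if y_raw is None:
            raise ValueError("labels are required")
    n = X.shape[0]
    if X.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if len(y_raw) != n:
        raise ValueError(f"got {len(y_raw)} labels for {n} items")
    classes, y = np.unique(np.asarray(y_raw), return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 distinct labels")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items ({n})")
    counts = np.bincount(y)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:  # stratification degrades gracefully to plain shuffled folds
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in splitter.split(X, y):
        cols = train  # feature columns restricted to the training fold
        clf = _make_classifier(classifier, len(train), knn_neighbors)
        clf.fit(X[np.ix_(train, cols)], y[train])
        accs.append(float(clf.score(X[np.ix_(test, cols)], y[test])))
    accs = np.array(accs)
    return CrossvalResult(fold_accuracies=accs, mean=float(accs.mean()), classifier=classifier, k=k)


# -- classical MDS ---------------------------------------------------------


def classical_mds(dissimilarity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared dissimilarities, B = -1/2 * J D^2 J, and embeds
    on the top ``dims`` eigenvectors scaled by sqrt(eigenvalue); negative
    eigenvalues (non-Euclidean part) are clipped to zero.  Axes are made
    deterministic by forcing the first non-zero loading of each axis positive.
    On Euclidean-realizable input the embedded pairwise distances reproduce
    the input exactly up to numerical tolerance.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"dissimilarity must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(d < -1e-12):
        raise ValueError("dissimilarities must be non-negative")
    n = d.shape[0]
    if not 1 <= dims <= n:
        raise ValueError(f"dims must be in [1, {n}], got {dims}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)
    for axis in range(coords.shape[1]):  # sign convention
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


def tss_to_dissimilarity(matrix: TSSMatrix | np.ndarray) -> np.ndarray:
    """d = 1 - similarity, with the diagonal forced to zero."""
    values = matrix.values if isinstance(matrix, TSSMatrix) else np.asarray(matrix, dtype=float)
    if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
        raise ValueError("similarity entries must lie in [0, 1]")
    d = 1.0 - np.clip(values, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d
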