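"""Group-organization scoring, anchor drift, and matrix-norm series."""

import numpy as np
import pandas as pd
import pytest

from tss import (
    Corpus,
    GroupAssignment,
    Message,
    QueryConfig,
    StreamModel,
    Topic,
    TSSMatrix,
    anchor_drift,
    group_performance,
    matrix_norm_series,
    simulate_stream,
    subnetwork_correlation,
    tss_matrix,
    tss_series,
)
from tss.corpus import Term


def make_matrix(values, items=None):
    values = np.asarray(values, dtype=float)
    items = items or [f"i{k}" for k in range(values.shape[0])]
    return TSSMatrix(vocabulary=tuple(Term(i) for i in items), time=0.0, values=values)


def block_matrix(n_groups, group_size, within=0.8, between=0.2):
    n = n_groups * group_size
    values = np.full((n, n), between)
    for g in range(n_groups):
        lo, hi = g * group_size, (g + 1) * group_size
        values[lo:hi, lo:hi] = within
    np.fill_diagonal(values, 1.0)
    return values


def assignment(n_groups, group_size):
    return GroupAssignment(
        {f"i{g * group_size + j}": f"g{g}" for g in range(n_groups) for j in range(group_size)}
    )


class TestGroupPerformance:
    def test_perfect_block_structure_scores_one(self):
        mat = make_matrix(block_matrix(8, 4))
        perf = group_performance(mat, assignment(8, 4))
        assert perf.mean == 1.0
        assert (perf.scores == 1.0).all()

    @pytest.mark.parametrize("n_groupmates, expected", [(3, 1.0), (2, 2 / 3), (1, 1 / 3), (0, 0.0)])
    def test_partial_credit_for_groupmates_in_top3(self, n_groupmates, expected):
        # start from a perfect 2-group block matrix, then rewire item 0's row so
        # exactly `n_groupmates` of its top-3 stay in its own group
        values = block_matrix(2, 4, within=0.8, between=0.2)
        outsiders = [4, 5, 6]
        for j, out in enumerate(outsiders):
            if j < 3 - n_groupmates:
                values[0, out] = values[out, 0] = 0.9  # outsider invades the top-3
        perf = group_performance(make_matrix(values), assignment(2, 4))
        assert perf.scores.iloc[0] == pytest.approx(expected)

    def test_missing_assignment_names_item(self):
        mat = make_matrix(block_matrix(2, 4))
        groups = GroupAssignment({f"i{k}": "g0" for k in range(7)})  # i7 missing
        with pytest.raises(ValueError, match="i7"):
            group_performance(mat, groups)

    def test_small_group_rejected(self):
        mat = make_matrix(block_matrix(2, 4))
        bad = GroupAssignment({f"i{k}": ("g0" if k < 5 else "g1") for k in range(8)})
        with pytest.raises(ValueError, match=">= 4"):
            group_performance(mat, bad)

    def test_ties_break_by_vocabulary_order(self):
        # all off-diagonal equal: each item's top-3 are the first three other items
        values = np.full((8, 8), 0.5)
        np.fill_diagonal(values, 1.0)
        perf = group_performance(make_matrix(values), assignment(2, 4))
        # item 0's top-3 = i1,i2,i3 (its groupmates); item 4's = i0,i1,i2 (none)
        assert perf.scores.loc["i0"] == 1.0
        assert perf.scores.loc["i4"] == 0.0

    def test_permutation_invariance_of_mean(self, rng):
        a = rng.random((8, 8))
        values = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(values, 1.0)
        base = group_performance(make_matrix(values), assignment(2, 4)).mean
        perm = rng.permutation(8)
        permuted = make_matrix(values[np.ix_(perm, perm)], items=[f"i{k}" for k in perm])
        assert group_performance(permuted, assignment(2, 4)).mean == pytest.approx(base)

    def test_random_matrix_chance_level_quick(self, rng):
        """Smoke check of the 3/31 chance level on 500 random 32x32 matrices
        (the tight version runs in the acceptance suite)."""
        vocab = tuple(Term(f"i{k}") for k in range(32))
        groups = assignment(8, 4)
        means = []
        for _ in range(500):
            a = rng.random((32, 32))
            values = (a + a.T) / 2
            np.fill_diagonal(values, 1.0)
            mat = TSSMatrix(vocabulary=vocab, time=0.0, values=values)
            means.append(group_performance(mat, groups).mean)
        assert np.mean(means) == pytest.approx(3 / 31, abs=0.02)


class TestAnchorDrift:
    def _corpus(self):
        # concept co-occurs only with g1 words
        msgs = []
        for i in range(60):
            msgs.append(Message(timestamp=10.0 * i, text="light lamp sun"))
            msgs.append(Message(timestamp=10.0 * i + 5.0, text="riot chaos"))
        return Corpus(msgs)

    def test_concept_tied_to_g1_gives_zero_g2_mean(self):
        frame = anchor_drift(
            self._corpus(), "light", ["lamp", "sun"], ["riot", "chaos"], [200.0, 400.0]
        )
        assert (frame["mean_tss_g2"] == 0.0).all()
        assert (frame["mean_tss_g1"] > 0.0).all()

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            anchor_drift(self._corpus(), "light", ["lamp", "sun"], ["sun", "riot"], [200.0])

    def test_concept_inside_group_rejected(self):
        with pytest.raises(ValueError, match="concept"):
            anchor_drift(self._corpus(), "light", ["light", "sun"], ["riot"], [200.0])

    def test_symmetric_groups_have_equal_means(self):
        """Two anchor sets playing interchangeable roles in the generative
        model track the concept equally, up to sampling error."""
        model = StreamModel(
            message_rate=2.0,
            topics=(
                Topic(0.5, {"c": 0.3, "a1": 0.3, "a2": 0.3}),
                Topic(0.5, {"c": 0.3, "b1": 0.3, "b2": 0.3}),
            ),
            vocabulary=("c", "a1", "a2", "b1", "b2"),
        )
        corpus = simulate_stream(model, seed=21, duration=6000)
        frame = anchor_drift(
            corpus, "c", ["a1", "a2"], ["b1", "b2"], np.linspace(2000, 5900, 40)
        )
        assert abs(frame["mean_tss_g1"].mean() - frame["mean_tss_g2"].mean()) < 0.05


class TestMatrixNorm:
    def test_zero_offdiagonal_gives_zero(self):
        values = np.eye(5)
        series = matrix_norm_series([make_matrix(values)])
        assert series["norm"].iloc[0] == 0.0

    def test_constant_offdiagonal_closed_form(self):
        m, c = 6, 0.4
        values = np.full((m, m), c)
        np.fill_diagonal(values, 1.0)
        series = matrix_norm_series([make_matrix(values)])
        assert series["norm"].iloc[0] == pytest.approx(c * np.sqrt(m * (m - 1)))

    def test_vocabulary_mismatch_rejected(self):
        a = make_matrix(np.eye(4), items=["a", "b", "c", "d"])
        b = make_matrix(np.eye(4), items=["a", "b", "c", "e"])
        with pytest.raises(ValueError, match="vocabulary"):
            matrix_norm_series([a, b])

    def test_shared_event_correlates_subnetwork_norms(self):
        """Two disjoint subnetworks sharing one global event show positively
        correlated norm series around the event window."""
        from tss.simulate import EventSchedule, Segment

        def model(boost):
            return StreamModel(
                message_rate=3.0,
                topics=(
                    Topic(0.5, {w: boost for w in ("a1", "a2", "a3", "a4")}),
                    Topic(0.5, {w: boost for w in ("b1", "b2", "b3", "b4")}),
                ),
                vocabulary=("a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"),
            )

        sched = EventSchedule(
            (Segment(0, 1500, model(0.2)), Segment(1500, 1800, model(0.7)),
             Segment(1800, 3600, model(0.2)))
        )
        times = list(np.linspace(1000, 3500, 26))
        rhos = []
        for seed in range(5):
            corpus = simulate_stream(sched, seed=seed)
            norms_a = matrix_norm_series(tss_series(corpus, ["a1", "a2", "a3", "a4"], times))
            norms_b = matrix_norm_series(tss_series(corpus, ["b1", "b2", "b3", "b4"], times))
            rhos.append(subnetwork_correlation(norms_a, norms_b)[0])
        assert np.mean(rhos) > 0.3


class TestSubnetworkCorrelation:
    def _frame(self, values):
        return pd.DataFrame({"time": np.arange(len(values), dtype=float), "norm": values})

    def test_identical_series_give_one(self):
        a = self._frame([1.0, 2.0, 3.0, 2.5])
        r, _ = subnetwork_correlation(a, a)
        assert r == pytest.approx(1.0)

    def test_negated_series_give_minus_one(self):
        a = self._frame([1.0, 2.0, 3.0, 2.5])
        b = self._frame([-1.0, -2.0, -3.0, -2.5])
        r, _ = subnetwork_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_too_few_aligned_points_rejected(self):
        a = self._frame([1.0, 2.0])
        with pytest.raises(ValueError, match="3 aligned"):
            subnetwork_correlation(a, a)

    def test_window_restricts_points(self):
        a = self._frame([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = self._frame([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        r_full, _ = subnetwork_correlation(a, b)
        r_win, _ = subnetwork_correlation(a, b, window=(0.0, 2.0))
        assert r_win == pytest.approx(1.0)
        assert r_full < 1.0

    def test_independent_noise_is_weakly_correlated(self, rng):
        a = self._frame(rng.normal(size=100))
        b = self._frame(rng.normal(size=100))
        r, _ = subnetwork_correlation(a, b)
        assert abs(r) < 0.25


class TestGroupAssignmentIO:
    def test_from_csv_and_lookup(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("item,group\nBrazil,A\nChile,B\n", encoding="utf-8")
        ga = GroupAssignment.from_csv(path)
        assert ga.group_of("brazil") == "A"

    def test_duplicate_item_names_row(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("item,group\na,A\na,B\n", encoding="utf-8")
        with pytest.raises(ValueError, match="row 3"):
            GroupAssignment.from_csv(path)
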