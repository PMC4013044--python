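import numpy as np
import pytest
from conftest import (
    brute_force_pairs,
    exact_null,
    quick_cohort,
    random_sequence,
    table_from,
    visit,
)

from homecage.errors import ConfigError, DataError
from homecage.event_log import make_roster
from homecage.social import (
    CornerSequence,
    Edge,
    PairCountMatrix,
    build_sequences,
    classify_edges,
    count_pairs,
    export_network,
    normalize_by_first,
    permutation_scores,
    read_network,
    score_pvalue,
    score_table,
    sum_counts,
)
from homecage.synthetic import inject_follower, simulate_cohort


def seq(corner, letters, times):
    return CornerSequence(
        corner=corner,
        codes=np.asarray(letters, dtype=np.int64),
        times=np.asarray(times, dtype=float),
    )


class TestBuildSequences:
    def test_empty_table(self):
        table = table_from([], roster=make_roster(["a"]))
        sequences = build_sequences(table)
        assert set(sequences) == {1, 2, 3, 4}
        assert all(len(s) == 0 for s in sequences.values())

    def test_one_visit_per_corner(self):
        table = table_from([visit("a", c, 100.0 * c) for c in (1, 2, 3, 4)])
        sequences = build_sequences(table)
        assert all(len(sequences[c]) == 1 for c in (1, 2, 3, 4))
        assert sequences[3].times[0] == 300.0

    def test_interleaved_ordering_matches_sort(self):
        rng = np.random.default_rng(4)
        # gaps > 1 s everywhere so the sub-second merge never fires
        records = [
            visit(f"m{rng.integers(4)}", int(rng.integers(1, 5)), 2.0 * k + rng.uniform(0, 0.5))
            for k in range(200)
        ]
        table = table_from(records)
        sequences = build_sequences(table)
        for corner in (1, 2, 3, 4):
            expected = sorted(r.t_start for r in records if r.corner == corner)
            assert list(sequences[corner].times) == expected

    def test_sub_second_same_mouse_reentry_merged(self):
        table = table_from(
            [visit("a", 1, 0.0, dur=0.2), visit("a", 1, 0.5), visit("b", 1, 30.0)]
        )
        sequences = build_sequences(table)
        assert len(sequences[1]) == 2  # the 0.5 s re-entry is merged away


ANIMALS = ["a", "b", "c"]


class TestCountPairs:
    def test_spec_example(self):
        s = seq(1, [0, 1, 0, 1], [0.0, 10.0, 25.0, 95.0])
        counts = count_pairs(s, ANIMALS)
        # ab once (gap 10), ba once (gap 15); final ab gap 70 excluded
        assert counts.counts[1, 0] == 1  # a first, b second
        assert counts.counts[0, 1] == 1
        assert counts.total_pairs == 2
        assert counts.total_adjacent == 3

    def test_singleton_sequence(self):
        counts = count_pairs(seq(1, [0], [5.0]), ANIMALS)
        assert counts.counts.sum() == 0

    def test_drop_repeats_example(self):
        s = seq(1, [0, 0, 1], [0.0, 5.0, 10.0])
        counts = count_pairs(s, ANIMALS, drop_repeats=True)
        assert counts.counts[0, 0] == 0  # aa gone
        assert counts.counts[1, 0] == 1  # ab counted with gap 10 from first 'a'

    def test_gap_boundaries_inclusive(self):
        s = seq(1, [0, 1, 0, 1], [0.0, 1.0, 31.0, 91.0])
        counts = count_pairs(s, ANIMALS)
        assert counts.total_pairs == 3  # gaps 1, 30, 60 all qualify

    def test_min_gap_exceeds_max_gap(self):
        with pytest.raises(ConfigError):
            count_pairs(seq(1, [0], [0.0]), ANIMALS, min_gap=5.0, max_gap=1.0)

    @pytest.mark.parametrize("drop_repeats", [False, True])
    def test_random_sequences_match_brute_force(self, drop_repeats):
        rng = np.random.default_rng(17)
        for _ in range(200):
            codes, times = random_sequence(rng, n_animals=4)
            s = seq(1, codes, times)
            got = count_pairs(s, list("abcd"), drop_repeats=drop_repeats)
            want = brute_force_pairs(codes, times, 4, drop_repeats=drop_repeats)
            np.testing.assert_array_equal(got.counts, want)
            assert got.total_pairs == want.sum()

    def test_sum_counts(self):
        m1 = count_pairs(seq(1, [0, 1], [0.0, 10.0]), ANIMALS)
        m2 = count_pairs(seq(2, [1, 2], [0.0, 20.0]), ANIMALS)
        total = sum_counts([m1, m2])
        assert total.counts.sum() == 2
        assert total.total_pairs == 2


class TestNormalizeByFirst:
    def test_column_arithmetic(self):
        counts = PairCountMatrix(
            animals=ANIMALS,
            counts=np.array([[2, 0, 0], [1, 0, 0], [1, 0, 0]]),
            total_pairs=4,
            total_adjacent=4,
        )
        mat, flagged = normalize_by_first(counts)
        np.testing.assert_allclose(mat[:, 0], [0.5, 0.25, 0.25])
        assert flagged == ["b", "c"]

    def test_all_zero(self):
        counts = PairCountMatrix(ANIMALS, np.zeros((3, 3), dtype=int), 0, 0)
        mat, flagged = normalize_by_first(counts)
        assert mat.sum() == 0
        assert flagged == ANIMALS

    def test_positive_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        counts = PairCountMatrix(ANIMALS, rng.integers(0, 9, (3, 3)), 0, 0)
        mat, _ = normalize_by_first(counts)
        sums = mat.sum(axis=0)
        for j in range(3):
            if counts.counts[:, j].sum() > 0:
                assert sums[j] == pytest.approx(1.0, abs=1e-12)


class TestPermutationScores:
    def test_identical_letters_zero_sd_sentinel(self):
        s = seq(1, [0, 0, 0, 0], [0.0, 10.0, 20.0, 30.0])
        scores = permutation_scores({1: s}, ["a", "b"], n_perm=10, seed=0)
        assert scores.scores[0, 0] == 0.0
        assert scores.zero_sd[0, 0]

    def test_n_perm_too_small(self):
        s = seq(1, [0, 1], [0.0, 10.0])
        with pytest.raises(ConfigError):
            permutation_scores({1: s}, ["a", "b"], n_perm=1)

    def test_no_qualifying_pairs_errors(self):
        s = seq(1, [0, 1], [0.0, 500.0])
        with pytest.raises(DataError):
            permutation_scores({1: s}, ["a", "b"], n_perm=10)

    def test_total_count_invariant_under_permutation(self):
        # all gaps qualify, no repeats dropped: every permutation keeps the
        # total pair count, so the null means must sum to the observed total
        s = seq(1, [0, 1, 0, 2, 1, 2], [0.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        scores = permutation_scores({1: s}, ANIMALS, n_perm=200, seed=3)
        assert scores.perm_mean.sum() == pytest.approx(scores.observed.sum())

    def test_exact_enumeration_aabb(self):
        # 4 slots 'a a b b', all gaps qualifying: null enumerable exactly
        codes = [0, 0, 1, 1]
        times = [0.0, 10.0, 20.0, 30.0]
        mean_exact, sd_exact = exact_null(codes, times, 2)
        s = seq(1, codes, times)
        n_perm = 10_000
        scores = permutation_scores({1: s}, ["a", "b"], n_perm=n_perm, seed=11)
        se_mean = sd_exact / np.sqrt(n_perm)
        np.testing.assert_array_less(
            np.abs(scores.perm_mean - mean_exact), 3 * se_mean + 1e-12
        )
        se_sd = sd_exact / np.sqrt(2 * n_perm)
        np.testing.assert_array_less(
            np.abs(scores.perm_sd - sd_exact), 3 * se_sd + 0.02
        )

    def test_deterministic_under_seed(self):
        s = seq(1, [0, 1, 2, 0, 1], [0.0, 5.0, 15.0, 25.0, 40.0])
        a = permutation_scores({1: s}, ANIMALS, n_perm=50, seed=9)
        b = permutation_scores({1: s}, ANIMALS, n_perm=50, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_injected_follower_scores_strong(self):
        config = quick_cohort(n_mice=6, seed=77, amp=12, floor=1.0)
        table = simulate_cohort(config)
        table = inject_follower(table, "m0", "m1", p_follow=0.9, seed=5)
        scores = score_table(table, n_perm=100, seed=1)
        i = table.animals.index("m1")  # second mouse (row)
        j = table.animals.index("m0")  # first mouse (column)
        assert scores.scores[i, j] > 3.5


class TestScorePvalue:
    def test_z2_gives_00455(self):
        assert round(score_pvalue(2.0), 4) == 0.0455

    def test_z0_gives_1(self):
        assert score_pvalue(0.0) == pytest.approx(1.0)

    def test_z35_below_00005(self):
        p = score_pvalue(3.5)
        assert p == pytest.approx(0.000465, abs=5e-7)
        assert p < 0.0005

    def test_symmetric(self):
        assert score_pvalue(-2.0) == score_pvalue(2.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            score_pvalue(float("nan"))


def make_scores(matrix, animals):
    from homecage.social import ScoreMatrix

    matrix = np.asarray(matrix, dtype=float)
    zeros = np.zeros_like(matrix)
    return ScoreMatrix(
        animals=animals,
        scores=matrix,
        perm_mean=zeros,
        perm_sd=zeros + 1,
        observed=zeros,
        n_perm=100,
        seed=0,
        zero_sd=np.zeros_like(matrix, dtype=bool),
    )


class TestClassifyEdges:
    def test_all_zero_scores_no_edges(self):
        edges, diag = classify_edges(make_scores(np.zeros((3, 3)), ANIMALS))
        assert edges == []
        assert list(diag["self_score"]) == [0.0, 0.0, 0.0]

    def test_weak_follow_edge(self):
        m = np.zeros((3, 3))
        m[1, 0] = 2.1  # a -> b
        edges, _ = classify_edges(make_scores(m, ANIMALS))
        assert len(edges) == 1
        e = edges[0]
        assert (e.source, e.target, e.kind, e.strength) == ("a", "b", "follow", "weak")

    def test_strong_avoid_edge(self):
        m = np.zeros((3, 3))
        m[0, 2] = -4.0  # c avoids ... c -> a direction
        edges, _ = classify_edges(make_scores(m, ANIMALS))
        e = edges[0]
        assert (e.source, e.target, e.kind, e.strength) == ("c", "a", "avoid", "strong")

    def test_diagonal_excluded_from_edges(self):
        m = np.eye(3) * 10.0
        edges, diag = classify_edges(make_scores(m, ANIMALS))
        assert edges == []
        assert list(diag["self_score"]) == [10.0, 10.0, 10.0]

    def test_brute_force_threshold_scan(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 3, (5, 5))
        animals = list("abcde")
        edges, _ = classify_edges(make_scores(m, animals))
        expected = set()
        for j in range(5):
            for i in range(5):
                if i != j and abs(m[i, j]) > 2.0:
                    expected.add((animals[j], animals[i]))
        assert {(e.source, e.target) for e in edges} == expected

    def test_invalid_thresholds(self):
        scores = make_scores(np.zeros((3, 3)), ANIMALS)
        with pytest.raises(ConfigError):
            classify_edges(scores, weak=-1.0)
        with pytest.raises(ConfigError):
            classify_edges(scores, weak=3.0, strong=2.0)


class TestExportNetwork:
    @pytest.fixture
    def annotations(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "animal_id": ANIMALS,
                "preference": [0.5, 0.3, 0.7],
                "weight_g": [26.0, 24.0, 25.5],
            }
        )

    def test_empty_edges_header_only(self, tmp_path, annotations):
        export_network([], annotations, tmp_path / "e.tsv", tmp_path / "n.tsv")
        lines = (tmp_path / "e.tsv").read_text().strip().split("\n")
        assert lines == ["source\ttarget\tscore\tkind\tstrength"]

    def test_one_edge_one_row(self, tmp_path, annotations):
        edge = Edge("a", "b", 2.5, "follow", "weak")
        export_network([edge], annotations, tmp_path / "e.tsv", tmp_path / "n.tsv")
        edges, nodes = read_network(tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert len(edges) == 1 and len(nodes) == 3

    def test_round_trip(self, tmp_path, annotations):
        edges_in = [
            Edge("a", "b", 2.5, "follow", "weak"),
            Edge("c", "a", -3.9, "avoid", "strong"),
        ]
        export_network(edges_in, annotations, tmp_path / "e.tsv", tmp_path / "n.tsv")
        edges_out, nodes = read_network(tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert edges_out == edges_in
        assert list(nodes["animal_id"]) == ANIMALS

    def test_unknown_node_errors(self, tmp_path, annotations):
        edge = Edge("a", "zz", 2.5, "follow", "weak")
        with pytest.raises(DataError):
            export_network([edge], annotations, tmp_path / "e.tsv", tmp_path / "n.tsv")
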