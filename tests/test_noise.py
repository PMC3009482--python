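import numpy as np
import pytest

from postmod.core import NEGATIVE, POSITIVE, NoiseParams
from postmod.noise_reduction import (
    IndirectMatrix,
    build_indirect_matrix,
    classify,
    classify_direct,
    indirect_scores,
    top_hits,
)
from postmod.synthetic import figure1_fixture
from .conftest import make_peptide


def toy_reference(labels, pid_prefix="R"):
    window = "A" * 20 + "S" + "A" * 20
    return [
        make_peptide(window, pid=f"{pid_prefix}{i:02d}", label=l)
        for i, l in enumerate(labels)
    ]


class TestTopHits:
    def test_simple_sorting(self):
        scores = np.array([0.9, 0.5, 0.1])
        assert top_hits(scores, ["A", "B", "C"], 2) == [0, 1]

    def test_boundary_tie_broken_by_key(self):
        scores = np.array([0.9, 0.5, 0.5])
        # B and C tie at 0.5: the lexicographically smaller key wins
        assert top_hits(scores, ["A", "C", "B"], 2) == [0, 2]

    def test_alpha_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="postmod"):
            hits = top_hits(np.array([1.0, 0.5]), ["A", "B"], 5)
        assert hits == [0, 1]
        assert "clamping" in caplog.text

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(3, 20))
            scores = rng.choice([0.0, 0.25, 0.5, 1.0], size=n)  # force ties
            keys = [f"K{i:02d}" for i in rng.permutation(n)]
            alpha = int(rng.integers(1, n + 1))
            oracle = sorted(range(n), key=lambda i: (-scores[i], keys[i]))[:alpha]
            assert top_hits(scores, keys, alpha) == oracle


class TestIndirectMatrix:
    def test_minimal_single_hit(self):
        keys = ["A", "B", "C"]
        ref = np.array([[0, 0.2, 0.9], [0.2, 0, 0.4], [0.9, 0.4, 0]])
        M = build_indirect_matrix([0], ref, keys, alpha=1)
        assert M.entries == {(0, 2): 0.9}

    def test_row_nonzero_bound(self):
        rng = np.random.default_rng(1)
        n, alpha = 12, 4
        ref = rng.random((n, n))
        ref = (ref + ref.T) / 2
        keys = [f"K{i:02d}" for i in range(n)]
        M = build_indirect_matrix([0, 3, 7], ref, keys, alpha)
        for j in [0, 3, 7]:
            row = [i for (jj, i) in M.entries if jj == j]
            assert len(row) <= alpha
            assert j not in row

    def test_pattern_matches_per_row_sort_oracle(self):
        rng = np.random.default_rng(2)
        n, alpha = 10, 3
        ref = rng.random((n, n))
        ref = (ref + ref.T) / 2
        keys = [f"K{i:02d}" for i in range(n)]
        hits = [1, 4, 8]
        M = build_indirect_matrix(hits, ref, keys, alpha)
        for j in hits:
            oracle = sorted(
                (i for i in range(n) if i != j), key=lambda i: (-ref[j, i], keys[i])
            )[:alpha]
            assert sorted(i for (jj, i) in M.entries if jj == j) == sorted(oracle)

    def test_self_relationship_rejected(self):
        with pytest.raises(ValueError, match="self"):
            IndirectMatrix(n=3, hits=[0], entries={(0, 0): 1.0})


class TestIndirectScores:
    def test_published_worked_example_value(self):
        # a positive peptide with positive partners 0.61 and 0.01 and a
        # negative partner 0.50 scores 10*(0.61+0.01) - 0.50 = 5.70
        labels = [POSITIVE, POSITIVE, POSITIVE, NEGATIVE]
        M = IndirectMatrix(
            n=4, hits=[0], entries={(0, 1): 0.61, (0, 2): 0.01, (0, 3): 0.50}
        )
        scores = indirect_scores(M, labels, weight=10.0)
        assert scores[0] == pytest.approx(5.70)

    def test_no_relationships_scores_zero(self):
        M = IndirectMatrix(n=3, hits=[], entries={})
        assert np.all(indirect_scores(M, [POSITIVE] * 3, 10.0) == 0)

    def test_matches_brute_force_contribution_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 10))
            labels = [POSITIVE if rng.random() < 0.4 else NEGATIVE for _ in range(n)]
            hits = list(rng.choice(n, size=min(3, n), replace=False))
            entries = {}
            for j in hits:
                for i in rng.choice(n, size=2, replace=False):
                    if int(i) != int(j):
                        entries[(int(j), int(i))] = float(rng.random())
            M = IndirectMatrix(n=n, hits=hits, entries=entries)
            weight = 7.5
            got = indirect_scores(M, labels, weight)
            want = np.zeros(n)
            for (j, i), v in entries.items():
                sign = 1.0 if labels[j] == labels[i] else -1.0
                want[j] += sign * (weight if labels[i] == POSITIVE else 1.0) * v
                want[i] += sign * (weight if labels[j] == POSITIVE else 1.0) * v
            assert np.allclose(got, want, atol=1e-12)

    def test_unlabeled_count_mismatch_rejected(self):
        M = IndirectMatrix(n=3, hits=[], entries={})
        with pytest.raises(ValueError):
            indirect_scores(M, [POSITIVE], 10.0)


class TestClassify:
    def test_three_of_four_positive_is_positive_call(self):
        fx = figure1_fixture()
        res = classify(fx.query, fx.reference, fx.query_scores, fx.ref_scores, fx.params)
        assert res.predicted_positive
        assert res.confidence == pytest.approx(0.75)
        assert res.n_pos_in_top_beta == 3

    def test_all_negative_top_beta(self):
        reference = toy_reference([POSITIVE] * 2 + [NEGATIVE] * 6)
        # query resembles only negatives
        qs = np.array([0.0, 0.0, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5])
        ref = np.zeros((8, 8))
        ref[2, 3] = ref[3, 2] = 0.9  # negative-negative signal
        params = NoiseParams(alpha=2, beta=2, gamma=0, weight=10.0)
        res = classify(None, reference, qs, ref, params)
        assert not res.predicted_positive
        assert res.confidence == 0.0

    def test_exact_gamma_is_negative_call(self):
        fx = figure1_fixture()
        params = NoiseParams(alpha=5, beta=4, gamma=3, weight=10.0)
        res = classify(fx.query, fx.reference, fx.query_scores, fx.ref_scores, params)
        assert res.n_pos_in_top_beta == 3  # equals gamma: strict inequality fails
        assert not res.predicted_positive

    def test_scale_equivariance(self):
        fx = figure1_fixture()
        base = classify(fx.query, fx.reference, fx.query_scores, fx.ref_scores, fx.params)
        for c in [0.2, 3.0, 117.0]:
            scaled = classify(
                fx.query, fx.reference, c * fx.query_scores, c * fx.ref_scores, fx.params
            )
            assert scaled.indirect_ranks == base.indirect_ranks
            assert scaled.predicted_positive == base.predicted_positive
            assert scaled.confidence == base.confidence

    def test_label_flip_invariance_with_unit_weight(self):
        # the sign rule depends only on label *equality*, so with weight 1 a
        # global label swap maps signal pairs to signal pairs and noise pairs
        # to noise pairs: every indirect score is unchanged
        labels = [POSITIVE, NEGATIVE, POSITIVE, NEGATIVE]
        flipped = [NEGATIVE, POSITIVE, NEGATIVE, POSITIVE]
        M = IndirectMatrix(
            n=4, hits=[0, 1], entries={(0, 1): 0.3, (0, 2): 0.7, (1, 3): 0.4, (1, 2): 0.2}
        )
        a = indirect_scores(M, labels, weight=1.0)
        b = indirect_scores(M, flipped, weight=1.0)
        assert np.allclose(a, b)

    def test_single_cross_pair_flip_negates_with_unit_weight(self):
        # antisymmetry does hold pairwise: flipping one endpoint of a lone
        # relationship toggles it between signal and noise
        M = IndirectMatrix(n=2, hits=[0], entries={(0, 1): 0.3})
        same = indirect_scores(M, [POSITIVE, POSITIVE], weight=1.0)
        cross = indirect_scores(M, [POSITIVE, NEGATIVE], weight=1.0)
        assert np.allclose(same, -cross)

    def test_zero_indirect_hit_ranks_below_supported_peptides(self):
        fx = figure1_fixture()
        res = classify(fx.query, fx.reference, fx.query_scores, fx.ref_scores, fx.params)
        ind = res.indirect_scores
        isolated = [i for i in range(len(fx.reference)) if ind[i] == 0]
        supported = [i for i in range(len(fx.reference)) if ind[i] > 0]
        for i in isolated:
            for j in supported:
                assert res.indirect_ranks.index(j) < res.indirect_ranks.index(i)

    def test_dense_equal_matrix_reduces_to_top_beta_majority(self):
        # all relationships equal and weight 1: the indirect score orders
        # peptides purely by how the labels of their partners balance out;
        # with all-same labels every peptide ties and ranking falls back to
        # direct similarity, i.e. a k-NN majority vote over the top beta
        labels = [POSITIVE] * 3 + [NEGATIVE] * 3
        reference = toy_reference(labels)
        qs = np.array([0.6, 0.5, 0.4, 0.9, 0.8, 0.7])
        n = 6
        entries = {
            (j, i): 1.0 for j in range(n) for i in range(n) if i != j
            if labels[j] == labels[i]
        }
        M = IndirectMatrix(n=n, hits=list(range(n)), entries=entries)
        ind = indirect_scores(M, labels, weight=1.0)
        # within each class all scores tie
        assert len(set(np.round(ind[:3], 9))) == 1
        assert len(set(np.round(ind[3:], 9))) == 1


class TestClassifyDirect:
    def test_agreeing_rankings_give_same_result(self):
        labels = [POSITIVE] * 2 + [NEGATIVE] * 4
        reference = toy_reference(labels)
        qs = np.array([0.9, 0.8, 0.1, 0.2, 0.3, 0.05])
        ref = np.zeros((6, 6))
        ref[0, 1] = ref[1, 0] = 0.9
        params = NoiseParams(alpha=2, beta=2, gamma=1, weight=10.0)
        d = classify_direct(None, reference, qs, params)
        n = classify(None, reference, qs, ref, params)
        assert d.predicted_positive == n.predicted_positive
        assert d.confidence == n.confidence

    def test_unsupported_high_direct_hit_is_demoted(self):
        # a negative with the best direct score but no indirect
        # relationships drops below positives with mutual support
        labels = [POSITIVE, POSITIVE, POSITIVE, NEGATIVE, NEGATIVE]
        reference = toy_reference(labels)
        qs = np.array([0.8, 0.7, 0.6, 0.95, 0.1])  # the negative R03 leads
        ref = np.zeros((5, 5))
        for i, j, v in [(0, 1, 0.9), (0, 2, 0.8), (1, 2, 0.85)]:
            ref[i, j] = ref[j, i] = v
        params = NoiseParams(alpha=4, beta=3, gamma=1, weight=10.0)
        d = classify_direct(None, reference, qs, params)
        n = classify(None, reference, qs, ref, params)
        assert d.direct_ranks[0] == 3
        assert n.indirect_ranks.index(3) > 0  # strictly demoted
        assert n.indirect_ranks.index(3) > n.indirect_ranks.index(0)

    def test_beta_clamping_shared_with_classify(self, caplog):
        labels = [POSITIVE, NEGATIVE]
        reference = toy_reference(labels)
        params = NoiseParams(alpha=1, beta=5, gamma=0, weight=10.0)
        with caplog.at_level("WARNING", logger="postmod"):
            d = classify_direct(None, reference, np.array([1.0, 0.5]), params)
        assert d.beta == 2
        assert "clamping" in caplog.text
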