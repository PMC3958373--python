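import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from rfcluster import (
    ClusterSet,
    ContingencyTable,
    contingency,
    match_precision_recall_f1,
    nmi,
    separation,
    sn_ppv_acc,
)


def fam(*clusters):
    return ClusterSet([set(c) for c in clusters])


class TestContingency:
    def test_identical_families_diagonal(self):
        k = fam("abc", "de")
        T = contingency(k, k)
        assert np.array_equal(np.diag(T.counts), T.known_sizes)

    def test_hand_counts(self):
        T = contingency(fam("abc", "de"), fam("ab", "cde"))
        assert T.counts.tolist() == [[2, 1], [0, 2]]
        assert T.known_sizes.tolist() == [3, 2]

    def test_disjoint_universes_zero_table(self):
        T = contingency(fam("ab"), fam("xy"), restrict_universe=False)
        assert T.counts.sum() == 0

    def test_universe_restriction_trims_unannotated(self):
        # predicted members outside the known universe do not depress PPV
        k = fam("abc")
        p = fam("abcxyz")
        sn, ppv, _ = sn_ppv_acc(contingency(k, p))
        assert ppv == 1.0
        _, ppv_raw, _ = sn_ppv_acc(contingency(k, p, restrict_universe=False))
        assert ppv_raw == 1.0  # counts only shared members either way

    def test_counts_bounded_by_known_size(self):
        T = contingency(fam("abcd"), fam("ab", "abcd"))
        assert np.all(T.counts <= T.known_sizes[:, None])


class TestNMI:
    def test_identical_partitions(self):
        P = fam("ab", "cd")
        assert nmi(P, fam("cd", "ab")) == pytest.approx(1.0)

    def test_independent_partitions(self):
        assert nmi(fam("12", "34"), fam("13", "24")) == pytest.approx(0.0)

    def test_one_trivial_partition(self):
        assert nmi(fam("12", "34"), fam("1234")) == pytest.approx(0.0)

    def test_both_trivial_partitions(self):
        assert nmi(fam("1234"), fam("1234")) == pytest.approx(1.0)

    def test_symmetry(self):
        P, Q = fam("abc", "de", "f"), fam("ab", "cdef")
        assert nmi(P, Q) == pytest.approx(nmi(Q, P))

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="partitions only|non-overlapping"):
            nmi(fam("ab", "bc"), fam("ab", "c"))

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            nmi(fam("ab"), fam("abc"))

    @settings(derandomize=True, max_examples=100)
    @given(
        labels=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=30
        )
    )
    def test_bounded_and_symmetric_on_arbitrary_partitions(self, labels):
        P = ClusterSet(
            [
                {f"v{i}" for i, (a, _) in enumerate(labels) if a == c}
                for c in {a for a, _ in labels}
            ]
        )
        Q = ClusterSet(
            [
                {f"v{i}" for i, (_, b) in enumerate(labels) if b == c}
                for c in {b for _, b in labels}
            ]
        )
        v = nmi(P, Q)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(nmi(Q, P))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        la = rng.integers(0, 4, size=n)
        lb = rng.integers(0, 3, size=n)
        P = ClusterSet(
            [{f"v{i}" for i in np.flatnonzero(la == c)} for c in np.unique(la)]
        )
        Q = ClusterSet(
            [{f"v{i}" for i in np.flatnonzero(lb == c)} for c in np.unique(lb)]
        )
        assert nmi(P, Q) == pytest.approx(
            normalized_mutual_info_score(la, lb, average_method="arithmetic")
        )


class TestMatching:
    def test_perfect_prediction(self):
        k = fam("abc", "de")
        ms = match_precision_recall_f1(k, k)
        assert (ms.precision, ms.recall, ms.f1) == (1.0, 1.0, 1.0)

    def test_partial_match_arithmetic(self):
        known = fam("abcd", "efgh")
        predicted = fam("abcd", "efgh", "xyzw")
        ms = match_precision_recall_f1(known, predicted)
        assert ms.precision == pytest.approx(2 / 3)
        assert ms.recall == pytest.approx(1.0)
        assert ms.f1 == pytest.approx(0.8)
        assert (ms.n_matched_predicted, ms.n_matched_known) == (2, 2)

    def test_no_matches_all_zero(self):
        ms = match_precision_recall_f1(fam("abcd"), fam("wxyz"))
        assert ms == (0.0, 0.0, 0.0, 0, 0)


class TestSnPpvAcc:
    def test_perfect_one_to_one(self):
        T = contingency(fam("abc", "de"), fam("abc", "de"))
        assert sn_ppv_acc(T) == (1.0, 1.0, 1.0)

    def test_hand_arithmetic(self):
        T = ContingencyTable(np.array([[2, 1], [0, 2]]), np.array([3, 2]))
        sn, ppv, acc = sn_ppv_acc(T)
        assert sn == pytest.approx(0.8)
        assert ppv == pytest.approx(0.8)
        assert acc == pytest.approx(0.8)

    def test_single_blanket_prediction(self):
        T = contingency(fam("abc", "de"), fam("abcde"))
        sn, ppv, _ = sn_ppv_acc(T)
        assert sn == 1.0
        assert ppv == pytest.approx(3 / 5)

    def test_zero_table_undefined(self):
        T = ContingencyTable(np.zeros((2, 2), dtype=int), np.array([2, 2]))
        with pytest.raises(ValueError):
            sn_ppv_acc(T)


class TestSeparation:
    def test_perfect_one_to_one(self):
        T = contingency(fam("abc", "de"), fam("abc", "de"))
        sk, sp, s = separation(T)
        assert (sk, sp, s) == (1.0, 1.0, 1.0)

    def test_hand_termwise_sum(self):
        T = ContingencyTable(np.array([[2, 1], [0, 2]]), np.array([3, 2]))
        sk, sp, s = separation(T)
        assert sk == pytest.approx(13 / 18)
        assert sp == pytest.approx(13 / 18)
        assert s == pytest.approx(13 / 18)

    def test_known_split_evenly(self):
        T = ContingencyTable(np.array([[1, 1]]), np.array([2]))
        sk, sp, s = separation(T)
        assert sk == pytest.approx(1.0)
        assert sp == pytest.approx(0.5)
        assert s == pytest.approx(math.sqrt(0.5))

    def test_zero_marginal_contributes_zero(self):
        T = ContingencyTable(np.array([[2, 0], [0, 0]]), np.array([2, 3]))
        sk, sp, s = separation(T)
        assert sk == pytest.approx(0.5)
        assert sp == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# brute-force oracles: literal loops, no vectorization, no shared code path


def brute_matching(known, predicted, omega=0.25):
    ncp = 0
    for p in predicted:
        for k in known:
            inter = len(p & k)
            if inter * inter / (len(p) * len(k)) >= omega:
                ncp += 1
                break
    nck = 0
    for k in known:
        for p in predicted:
            inter = len(p & k)
            if inter * inter / (len(p) * len(k)) >= omega:
                nck += 1
                break
    prec, rec = ncp / len(predicted), nck / len(known)
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return prec, rec, f1


def brute_sn_ppv_sep(known, predicted):
    universe = set().union(*[set(k) for k in known])
    pred = [set(p) & universe for p in predicted]
    T = [[len(set(k) & p) for p in pred] for k in known]
    n, m = len(known), len(pred)
    sn = sum(max(row) for row in T) / sum(len(k) for k in known)
    total = sum(sum(row) for row in T)
    ppv_num = sum(max(T[i][j] for i in range(n)) for j in range(m))
    ppv = ppv_num / total if total else None
    sep_total = 0.0
    for i in range(n):
        row_sum = sum(T[i])
        for j in range(m):
            col_sum = sum(T[x][j] for x in range(n))
            if row_sum and col_sum:
                sep_total += (T[i][j] / row_sum) * (T[i][j] / col_sum)
    return sn, ppv, sep_total / n, sep_total / m


def random_family(rng, universe, max_clusters=6):
    fam_ = []
    for _ in range(rng.integers(1, max_clusters + 1)):
        size = int(rng.integers(1, 8))
        fam_.append(set(rng.choice(universe, size=size, replace=False)))
    return fam_


class TestBruteForceAgreement:
    def test_200_random_family_pairs(self):
        """Optimized metrics agree with literal double-loop oracles and
        stay inside [0, 1] on 200 random cluster-family pairs."""
        rng = np.random.default_rng(2024)
        universe = np.array([f"p{i}" for i in range(25)])
        for _ in range(200):
            known = random_family(rng, universe)
            predicted = random_family(rng, universe)
            k, p = ClusterSet(known), ClusterSet(predicted)
            ms = match_precision_recall_f1(k, p)
            bp, br, bf = brute_matching(known, predicted)
            assert ms.precision == pytest.approx(bp)
            assert ms.recall == pytest.approx(br)
            assert ms.f1 == pytest.approx(bf)
            T = contingency(k, p)
            if T.counts.sum() == 0:
                continue
            sn, ppv, acc = sn_ppv_acc(T)
            b_sn, b_ppv, b_sk, b_sp = brute_sn_ppv_sep(known, predicted)
            assert sn == pytest.approx(b_sn)
            assert ppv == pytest.approx(b_ppv)
            assert acc == pytest.approx(math.sqrt(b_sn * b_ppv))
            sk, sp, s = separation(T)
            assert sk == pytest.approx(b_sk)
            assert sp == pytest.approx(b_sp)
            for val in (sn, ppv, acc, sk, sp, s, ms.precision, ms.recall, ms.f1):
                assert -1e-12 <= val <= 1 + 1e-12

    def test_cluster_order_invariance(self):
        rng = np.random.default_rng(5)
        universe = np.array([f"p{i}" for i in range(20)])
        known = random_family(rng, universe)
        predicted = random_family(rng, universe)
        k1, p1 = ClusterSet(known), ClusterSet(predicted)
        k2 = ClusterSet(list(reversed(known)))
        p2 = ClusterSet(list(reversed(predicted)))
        assert match_precision_recall_f1(k1, p1)[:3] == match_precision_recall_f1(
            k2, p2
        )[:3]
        if contingency(k1, p1).counts.sum():
            assert sn_ppv_acc(contingency(k1, p1)) == sn_ppv_acc(
                contingency(k2, p2)
            )
            assert separation(contingency(k1, p1)) == pytest.approx(
                separation(contingency(k2, p2))
            )


class TestMonotoneBehaviour:
    def test_sn_grows_as_prediction_absorbs_true_members(self):
        known = fam("abcdef")
        prev = 0.0
        for size in range(2, 7):
            pred = ClusterSet([set("abcdef"[:size])])
            sn, _, _ = sn_ppv_acc(contingency(known, pred))
            assert sn >= prev
            prev = sn

    def test_ppv_drops_when_prediction_mixes_complexes(self):
        known = fam("abc", "def")
        pure = ClusterSet([{"a", "b", "c"}])
        mixed = ClusterSet([{"a", "b", "c", "d", "e"}])
        _, ppv_pure, _ = sn_ppv_acc(contingency(known, pure))
        _, ppv_mixed, _ = sn_ppv_acc(contingency(known, mixed))
        assert ppv_mixed <= ppv_pure
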