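from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from splicevo.errors import InputError
from splicevo.phylogeny import (
    bootstrap_support,
    dollo_history,
    fitch_cost,
    infer_origin_model,
    nj_tree,
    p_distance_matrix,
    root_with_outgroup,
    tree_splits,
)
from conftest import random_rooted_tree
from oracles import dollo_exhaustive


class TestPDistance:
    def test_identical_and_simple_pairs(self):
        d = p_distance_matrix({"a": "AAAA", "b": "AAAA", "c": "AAAT"})
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == pytest.approx(0.25)
        assert (np.diag(d.values) == 0).all()

    def test_gapped_columns_excluded(self):
        d = p_distance_matrix({"a": "AA-A", "b": "AT-A"})
        assert d.loc["a", "b"] == pytest.approx(1 / 3)

    def test_no_comparable_columns_error(self):
        with pytest.raises(InputError):
            p_distance_matrix({"a": "A-", "b": "-A"})

    def test_random_pair_matches_column_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT-"), 60))
            b = "".join(rng.choice(list("ACGT-"), 60))
            ok = [i for i in range(60) if a[i] != "-" and b[i] != "-"]
            if not ok:
                continue
            expect = sum(a[i] != b[i] for i in ok) / len(ok)
            d = p_distance_matrix({"a": a, "b": b})
            assert d.loc["a", "b"] == pytest.approx(expect)


class TestNeighborJoining:
    def test_additive_matrix_recovers_split(self):
        # distances from tree ((A:1,B:2):1,(C:1,D:3))
        dm = pd.DataFrame(
            [[0, 3, 3, 5], [3, 0, 4, 6], [3, 4, 0, 4], [5, 6, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = nj_tree(dm)
        splits = tree_splits(tree, frozenset("ABCD"))
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits

    def test_matches_reference_nj_on_random_additive_matrices(self):
        """Cross-check topologies against scikit-bio's NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            tree = random_rooted_tree(rng, n)
            for node in tree.traverse():
                if node.length is not None:
                    node.length = float(rng.uniform(0.5, 3.0))
            names = [t.name for t in tree.tips()]
            dm = np.zeros((n, n))
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    if i < j:
                        d = tree.find(a).distance(tree.find(b))
                        dm[i, j] = dm[j, i] = d
            ours = nj_tree(pd.DataFrame(dm, index=names, columns=names))
            ref = skbio_nj(DistanceMatrix(dm, names))
            taxa = frozenset(names)
            assert tree_splits(ours, taxa) == tree_splits(ref, taxa)

    def test_equal_distances_deterministic(self):
        dm = pd.DataFrame(np.ones((5, 5)) - np.eye(5),
                          index=list("ABCDE"), columns=list("ABCDE"))
        t1 = str(nj_tree(dm))
        t2 = str(nj_tree(dm))
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        dm = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(InputError):
            nj_tree(dm)


class TestBootstrap:
    def test_clear_split_has_high_support(self):
        rng = np.random.default_rng(4)
        block_a = "".join(rng.choice(list("ACGT"), 120))
        block_b = "".join(rng.choice(list("ACGT"), 120))
        msa = {"A": block_a, "B": block_a, "C": block_b, "D": block_b}
        support = bootstrap_support(msa, n_reps=100, seed=7)
        split = frozenset({"C", "D"})
        assert support.get(split, 0.0) >= 0.8

    def test_single_replicate_support_is_binary(self):
        rng = np.random.default_rng(5)
        msa = {k: "".join(rng.choice(list("ACGT"), 50)) for k in "ABCDE"}
        support = bootstrap_support(msa, n_reps=1, seed=1)
        assert set(support.values()) <= {0.0, 1.0}

    def test_nreps_zero_rejected(self):
        with pytest.raises(InputError):
            bootstrap_support({"a": "AC", "b": "AC", "c": "AG"}, n_reps=0)


class TestDollo:
    def test_gain_at_mrca_no_losses(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        h = dollo_history(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert h.gain_branch == frozenset({"A", "B"})
        assert h.loss_branches == set() and h.cost == 0

    def test_gain_at_root_with_two_losses(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        h = dollo_history(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert h.gain_branch == frozenset({"A", "B", "C", "D"})
        assert h.loss_branches == {frozenset({"B"}), frozenset({"D"})}
        assert h.cost == 2

    def test_all_absent_gives_empty_history(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        h = dollo_history(tree, {n: 0 for n in "ABCD"})
        assert h.gain_branch is None and h.cost == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            n = int(rng.integers(4, 11))
            tree = random_rooted_tree(rng, n)
            leaves = [t.name for t in tree.tips()]
            for _ in range(4):
                states = {l: int(rng.integers(0, 2)) for l in leaves}
                if not any(states.values()):
                    continue
                h = dollo_history(tree, states)
                cost, gain, losses = dollo_exhaustive(tree, states)
                assert h.cost == cost
                assert h.gain_branch == gain
                assert frozenset(h.loss_branches) == losses

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        tree = random_rooted_tree(rng, 8)
        leaves = [t.name for t in tree.tips()]
        states = {l: int(rng.integers(0, 2)) for l in leaves}
        if not any(states.values()):
            states[leaves[0]] = 1
        h = dollo_history(tree, states)

        perm = {l: f"X{i}" for i, l in enumerate(leaves)}
        relabeled = tree.copy()
        for t in relabeled.tips():
            t.name = perm[t.name]
        h2 = dollo_history(relabeled, {perm[l]: s for l, s in states.items()})
        assert h2.gain_branch == frozenset(perm[l] for l in h.gain_branch)
        assert {frozenset(perm[l] for l in b) for b in h.loss_branches} == set(
            h2.loss_branches
        )

    def test_fitch_cost_simple(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        assert fitch_cost(tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1
        assert fitch_cost(tree, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2


class TestOriginModel:
    def test_single_group_is_single_origin(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        model = infer_origin_model(tree, {"P1": {"A", "B", "C", "D"}})
        assert model.verdict == "SINGLE_ORIGIN"

    def test_disjoint_clades_without_loss_are_independent(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        model = infer_origin_model(tree, {"P1": {"A", "B"}, "P2": {"C", "D"}})
        assert model.verdict == "INDEPENDENT"
        assert model.linked_pairs == []

    def test_gain_on_loss_branch_is_replacement(self):
        """An ancestral group lost exactly where a new one was gained: the
        SRSF4/5/6-like configuration."""
        tree = TreeNode.read(
            ["((fungal,anemone_like),((v1_A,v2_A),(v1_B,v2_B)));"],
            convert_underscores=False,
        )
        groups = {
            "ancestral": {"fungal", "anemone_like", "v1_A", "v2_A"},
            "new": {"v1_B", "v2_B"},
        }
        model = infer_origin_model(tree, groups)
        assert model.verdict == "REPLACEMENT"
        (gi, gj, branch) = model.linked_pairs[0]
        assert (gi, gj) == ("ancestral", "new")
        assert branch == frozenset({"v1_B", "v2_B"})

    def test_unknown_leaf_rejected(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        with pytest.raises(InputError):
            infer_origin_model(tree, {"P1": {"A", "Z"}})

    def test_no_groups(self):
        tree = TreeNode.read(["((A,B),(C,D));"])
        assert infer_origin_model(tree, {}).verdict == "NO_EVENTS"


def test_root_with_outgroup_places_outgroup_at_root():
    tree = TreeNode.read(["(A:1,B:1,(C:1,D:1):1);"])
    rooted = root_with_outgroup(tree, "A")
    assert len(rooted.children) == 2
    assert {t.name for t in rooted.children[0].tips(include_self=True)} == {"A"} or {
        t.name for t in rooted.children[1].tips(include_self=True)
    } == {"A"}
    with pytest.raises(InputError):
        root_with_outgroup(tree, "nope")
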