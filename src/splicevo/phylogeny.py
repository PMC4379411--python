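"""Trees, bootstrap supports, and Dollo gain/loss histories.

The analytical core is the reconstruction of presence/absence histories of
binary characters (intron positions, poison-exon homology groups) under Dollo
parsimony — one gain, any number of losses — and the family-level verdict on
how unproductive splicing evolved: a single origin, independent origins, or
replacement (an ancestral event lost on a branch where a new one arose).

Trees are :class:`skbio.TreeNode` objects.  External trees (e.g. from a
maximum-likelihood program) are accepted as newick; a built-in p-distance +
neighbor-joining combination serves when no external tree is supplied.
Branches are identified by the set of leaf names below them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InputError

Clade = frozenset  # of leaf names; identifies the branch above that clade


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------


def p_distance_matrix(msa: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise mismatch fraction over columns where neither row is gapped."""
    names = list(msa)
    if len(names) < 2:
        raise InputError("need at least two sequences")
    arrs = {n: np.frombuffer(msa[n].upper().encode(), dtype=np.uint8) for n in names}
    gap = ord("-")
    m = len(names)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = arrs[names[i]], arrs[names[j]]
            ok = (a != gap) & (b != gap)
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise InputError(
                    f"no comparable columns between {names[i]} and {names[j]}"
                )
            d = float(np.mean(a[ok] != b[ok]))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=names, columns=names)


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the smallest (row, column) index
    pair; negative branch lengths are clamped to zero with a warning.  The
    result is an unrooted tree (trifurcating root) for >= 4 taxa.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise InputError("distance matrix must be square and symmetric")
    names = list(dist.index)
    n = len(names)
    if n < 2:
        raise InputError("need at least two taxa")

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            return 0.0
        return x

    nodes = [TreeNode(name=nm) for nm in names]
    active = list(range(n))
    D = d.copy()

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ii in range(k):
            for jj in range(ii + 1, k):
                if best is None or q[ii, jj] < q[best] - 1e-12:
                    best = (ii, jj)
        ii, jj = best
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = clamp(dij / 2 + (r[ii] - r[jj]) / (2 * (k - 2)))
        lj = clamp(dij - (dij / 2 + (r[ii] - r[jj]) / (2 * (k - 2))))
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to remaining taxa
        new_row = np.zeros(D.shape[0])
        for mm in active:
            if mm in (i, j):
                continue
            new_row[mm] = (D[i, mm] + D[j, mm] - dij) / 2
        D[i, :] = new_row
        D[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    root = TreeNode()
    if len(active) == 3:
        i, j, k3 = active
        dij, dik, djk = D[i, j], D[i, k3], D[j, k3]
        nodes[i].length = clamp((dij + dik - djk) / 2)
        nodes[j].length = clamp((dij + djk - dik) / 2)
        nodes[k3].length = clamp((dik + djk - dij) / 2)
        root.extend([nodes[i], nodes[j], nodes[k3]])
    elif len(active) == 2:
        i, j = active
        nodes[i].length = clamp(D[i, j] / 2)
        nodes[j].length = clamp(D[i, j] / 2)
        root.extend([nodes[i], nodes[j]])
    else:  # single taxon
        root = nodes[active[0]]
    return root


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root an (unrooted) tree on the branch above the named outgroup leaf."""
    try:
        node = tree.find(outgroup)
    except Exception as exc:
        raise InputError(f"outgroup {outgroup!r} not found in tree") from exc
    return tree.root_at(node, above=True)


# ---------------------------------------------------------------------------
# Splits and bootstrap
# ---------------------------------------------------------------------------


def tree_splits(tree: TreeNode, taxa: frozenset | None = None) -> set[Clade]:
    """Non-trivial bipartitions, each canonicalized to the side that does not
    contain the lexicographically smallest taxon."""
    if taxa is None:
        taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    splits: set[Clade] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(taxa - side)
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    msa: Mapping[str, str], n_reps: int = 100, seed: int = 0
) -> dict[Clade, float]:
    """Column-resampling bootstrap support for each split of the full tree.

    Replicate ``r`` uses seed ``seed + r`` so replicates are reproducible
    independently of execution order.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    names = list(msa)
    length = len(next(iter(msa.values())))
    taxa = frozenset(names)
    full = nj_tree(p_distance_matrix(msa))
    targets = tree_splits(full, taxa)
    counts = {s: 0 for s in targets}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, length, size=length)
        resampled = {n: "".join(msa[n][c] for c in cols) for n in names}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = nj_tree(p_distance_matrix(resampled))
        rep_splits = tree_splits(rep_tree, taxa)
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    return {s: c / n_reps for s, c in counts.items()}


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------


@dataclass
class EventHistory:
    """Single-gain history of a binary character on a rooted tree."""

    character: str
    gain_branch: Clade | None  # leaf set below the gain branch; None if all-absent
    loss_branches: set[Clade] = field(default_factory=set)
    cost: int = 0  # number of losses
    fitch_cost: int = 0  # unrestricted-parsimony change count, for comparison
    present_leaves: frozenset = frozenset()


def _clade(node: TreeNode) -> Clade:
    return frozenset(t.name for t in node.tips(include_self=True))


def fitch_cost(tree: TreeNode, states: Mapping[str, int]) -> int:
    """Minimal number of state changes under unordered (Fitch) parsimony."""
    cost = 0

    def post(node: TreeNode) -> set[int]:
        nonlocal cost
        if node.is_tip():
            return {int(states[node.name])}
        child_sets = [post(c) for c in node.children]
        inter = set.intersection(*child_sets)
        if inter:
            return inter
        cost += 1
        return set.union(*child_sets)

    post(tree)
    return cost


def dollo_history(
    tree: TreeNode, states: Mapping[str, int], character: str = ""
) -> EventHistory:
    """Reconstruct the minimal single-gain history of a binary character.

    The gain is placed on the branch above the most recent common ancestor of
    all present leaves; losses are the minimal set of branches inside that
    clade subtending only absent leaves (maximal pure-absent subtrees).  The
    resulting loss count is minimal among all single-gain scenarios.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in states]
    if missing:
        raise InputError(f"no state for leaves {missing[:3]}")
    ones = frozenset(l for l in leaves if states[l] == 1)
    if not ones:
        return EventHistory(character=character, gain_branch=None)

    if len(ones) == 1:
        mrca = tree.find(next(iter(ones)))
    else:
        mrca = tree.lca(list(ones))

    losses: set[Clade] = set()

    def collect(node: TreeNode) -> None:
        below = _clade(node)
        if not below & ones:
            losses.add(below)
            return
        for c in node.children:
            collect(c)

    for c in mrca.children:
        collect(c)

    return EventHistory(
        character=character,
        gain_branch=_clade(mrca),
        loss_branches=losses,
        cost=len(losses),
        fitch_cost=fitch_cost(tree, states),
        present_leaves=ones,
    )


# ---------------------------------------------------------------------------
# Origin-model inference
# ---------------------------------------------------------------------------


@dataclass
class OriginModel:
    """Family-level verdict on how unproductive splicing evolved.

    ``SINGLE_ORIGIN``: one homology group explains every event.
    ``INDEPENDENT``: several groups, none linked to an ancestral loss.
    ``REPLACEMENT``: some group's gain lies on (or below) a branch where an
    older group was lost — the ancestral regulation was replaced in place.
    """

    verdict: str
    linked_pairs: list[tuple[str, str, Clade]] = field(default_factory=list)
    histories: dict[str, EventHistory] = field(default_factory=dict)
    ambiguous: list[str] = field(default_factory=list)


def infer_origin_model(
    tree: TreeNode,
    groups: Mapping[str, set[str] | frozenset],
    linkage: str = "strict",
) -> OriginModel:
    """Classify a family's unproductive-splicing history from event groups.

    ``groups`` maps each event homology group to the leaves carrying it.
    With ``linkage="strict"`` a replacement requires the new group's gain on
    the lost branch or one of its descendants; ``linkage="clade"`` relaxes
    this to gains anywhere inside the clade containing the loss (one level
    up), acknowledging uncertain branch resolution.
    """
    if not groups:
        return OriginModel(verdict="NO_EVENTS")
    leaf_names = {t.name for t in tree.tips()}
    histories: dict[str, EventHistory] = {}
    for name, members in groups.items():
        unknown = set(members) - leaf_names
        if unknown:
            raise InputError(f"group {name!r} references unknown leaves {unknown}")
        states = {l: (1 if l in members else 0) for l in leaf_names}
        histories[name] = dollo_history(tree, states, character=name)

    # flag groups where unrestricted parsimony beats the single-gain history
    ambiguous = [
        n for n, h in histories.items() if h.gain_branch and h.fitch_cost < 1 + h.cost
    ]

    if len(groups) == 1:
        return OriginModel(
            verdict="SINGLE_ORIGIN", histories=histories, ambiguous=ambiguous
        )

    linked: list[tuple[str, str, Clade]] = []
    for gi, hi in histories.items():
        for gj, hj in histories.items():
            if gi == gj or hj.gain_branch is None:
                continue
            for loss in hi.loss_branches:
                target = loss
                if linkage == "clade":
                    # widen to the clade from which the branch descends
                    target = hi.gain_branch if hi.gain_branch else loss
                if hj.gain_branch <= target:
                    linked.append((gi, gj, loss))
                    break
    verdict = "REPLACEMENT" if linked else "INDEPENDENT"
    return OriginModel(
        verdict=verdict, linked_pairs=linked, histories=histories, ambiguous=ambiguous
    )
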