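"""Independent brute-force oracles used to validate the library.

Each oracle is written as directly as possible (linear scans, explicit
enumeration, hand-typed codon table) and never calls the code path it
checks.
"""

from __future__ import annotations

import itertools

# hand-typed standard genetic code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(mrna: str, offset: int) -> str:
    """Codon-by-codon lookup; stops at (and excludes) the first stop."""
    out = []
    for i in range(offset, len(mrna) - 2, 3):
        aa = CODON_TABLE[mrna[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def prefix_sum_junctions(block_lengths: list[int]) -> list[int]:
    out, acc = [], 0
    for length in block_lengths[:-1]:
        acc += length
        out.append(acc)
    return out


def residue_to_column_oracle(row: str, residue_index: int) -> int:
    """Scan the aligned row counting non-gap characters."""
    seen = -1
    for col, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == residue_index:
                return col
    raise IndexError(residue_index)


def nmd_verdict_oracle(
    mrna: str,
    cds_offset: int,
    block_lengths: list[int],
    polyA: bool,
    threshold: int,
    ref_stop_pos: int | None = None,
) -> str:
    """Linear-scan re-statement of the junction rule.

    ``ref_stop_pos`` is the mRNA coordinate of the first nt 3' of the
    annotated stop, when known.
    """
    stop = None
    i = cds_offset
    while i + 3 <= len(mrna):
        if CODON_TABLE.get(mrna[i : i + 3]) == "*":
            stop = i + 3
            break
        i += 3
    if stop is None:
        return "no_stop"
    if ref_stop_pos is not None and stop == ref_stop_pos:
        return "PRODUCTIVE"
    junctions = prefix_sum_junctions(block_lengths)
    down = [j for j in junctions if j >= stop]
    if not down:
        return "ESCAPE_TRUNCATED" if polyA else "ESCAPE_LAST_EXON"
    return "NMD_TARGET" if max(junctions) - stop >= threshold else "PRODUCTIVE"


# ---------------------------------------------------------------------------
# Dollo parsimony by exhaustive enumeration
# ---------------------------------------------------------------------------


def dollo_exhaustive(tree, states: dict[str, int]):
    """Minimal single-gain history by enumerating internal node states.

    Returns (cost, gain_clade, loss_clades) where clades are frozensets of
    leaf names below the gain / loss branches.  The tree is a rooted
    skbio TreeNode; the state above the root is 0, so a gain on the root
    branch corresponds to root state 1.
    """
    internals = list(tree.non_tips(include_self=True))
    leaves = list(tree.tips())
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assignment)}
        for leaf in leaves:
            state[id(leaf)] = states[leaf.name]
        gains = []
        losses = []
        ok = True
        # virtual edge above the root: ancestral state 0
        nodes = [(None, tree)]
        while nodes:
            parent_state, node = nodes.pop()
            s = state[id(node)]
            up = 0 if parent_state is None else parent_state
            if up == 0 and s == 1:
                gains.append(node)
            elif up == 1 and s == 0:
                losses.append(node)
            for c in node.children:
                nodes.append((s, c))
        if len(gains) != 1:
            ok = False
        if ok:
            cost = len(losses)
            if best is None or cost < best[0]:
                clade = frozenset(t.name for t in gains[0].tips(include_self=True))
                loss_clades = frozenset(
                    frozenset(t.name for t in n.tips(include_self=True)) for n in losses
                )
                best = (cost, clade, loss_clades)
    return best


# ---------------------------------------------------------------------------
# Conservation oracles
# ---------------------------------------------------------------------------


def perfect_runs_oracle(rows: list[str], min_len: int) -> list[tuple[int, int]]:
    n = len(rows[0])
    runs = []
    start = None
    for i in range(n + 1):
        same = (
            i < n
            and all(r[i] == rows[0][i] for r in rows)
            and rows[0][i] != "-"
        )
        if same and start is None:
            start = i
        elif not same and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def identity_profile_oracle(rows: list[str], window: int) -> list[float]:
    n = len(rows)
    length = len(rows[0])
    raw = []
    for col in range(length):
        agree = 0
        pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                if rows[i][col] == rows[j][col] != "-":
                    agree += 1
        raw.append(agree / pairs)
    if window <= 1:
        return raw
    half = window // 2
    out = []
    for col in range(length):
        lo = max(0, col - half)
        hi = min(length - 1, col + (window - 1 - half))
        vals = raw[lo : hi + 1]
        out.append(sum(vals) / len(vals))
    return out


def percentile_oracle(lengths: list[int], query: int) -> tuple[float, float]:
    srt = sorted(lengths)
    shorter = sum(1 for x in srt if x < query)
    at_least = sum(1 for x in srt if x >= query)
    return shorter / len(srt), at_least / len(srt)
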