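"""Sequence conservation: ultraconserved runs, identity profiles, intron lengths.

Ultraconserved elements are classically defined as runs of at least 200 nt of
perfect identity between distant genomes.  Here the scan operates on any
supplied alignment; a gap is never identity, so gaps break runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class PerfectRun:
    """Maximal alignment interval over which all rows are identical, no gaps.

    ``seq_coords`` gives the equivalent gap-excluded interval per sequence.
    """

    start: int
    end: int
    seq_coords: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_rows(aln) -> tuple[list[str], list[str]]:
    if isinstance(aln, Mapping):
        names = list(aln)
        rows = [aln[n] for n in names]
    else:
        rows = list(aln)
        names = [f"seq{i}" for i in range(len(rows))]
    if len(rows) < 2:
        raise InputError("alignment needs at least two rows")
    if len({len(r) for r in rows}) != 1:
        raise InputError("alignment rows have unequal lengths")
    return names, rows


def perfect_identity_runs(aln, min_len: int = 200) -> list[PerfectRun]:
    """Maximal columns runs where every row agrees and none is a gap."""
    names, rows = _as_rows(aln)
    arrs = [np.frombuffer(r.upper().encode(), dtype=np.uint8) for r in rows]
    agree = np.ones(len(arrs[0]), dtype=bool)
    gap = ord("-")
    first = arrs[0]
    agree &= first != gap
    for a in arrs[1:]:
        agree &= (a == first) & (a != gap)

    # per-row gap-excluded coordinate of each column
    ungapped = [np.cumsum(a != gap) for a in arrs]

    runs: list[PerfectRun] = []
    n = len(agree)
    i = 0
    while i < n:
        if agree[i]:
            j = i
            while j < n and agree[j]:
                j += 1
            if j - i >= min_len:
                coords = {
                    name: (int(u[i] - 1), int(u[j - 1]))
                    for name, u in zip(names, ungapped)
                }
                runs.append(PerfectRun(start=i, end=j, seq_coords=coords))
            i = j
        else:
            i += 1
    return runs


def column_identity_profile(aln, window: int = 25) -> np.ndarray:
    """Per-column fraction of row pairs in agreement, smoothed.

    Gaps count as disagreement (including gap-vs-gap).  Smoothing is a
    centered moving average truncated at the alignment edges; the output has
    the alignment's length.  ``window=1`` (or 0) disables smoothing.
    """
    names, rows = _as_rows(aln)
    arrs = np.array([np.frombuffer(r.upper().encode(), dtype=np.uint8) for r in rows])
    gap = ord("-")
    n = len(rows)
    n_pairs = n * (n - 1) // 2
    agree = np.zeros(arrs.shape[1], dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            agree += (arrs[i] == arrs[j]) & (arrs[i] != gap)
    raw = agree / n_pairs
    if window <= 1:
        return raw
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    length = len(raw)
    idx = np.arange(length)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window - 1 - half), length - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def intron_length_percentile(
    lengths: Sequence[int], query: int
) -> tuple[float, float]:
    """Where an intron length sits in a length distribution.

    Returns ``(percentile, top_fraction)`` where ``percentile`` is the
    fraction of introns strictly shorter than the query and ``top_fraction``
    the fraction at least as long; an intron is "in the longest q" iff
    ``top_fraction <= q``.
    """
    if len(lengths) == 0:
        raise InputError("empty length list")
    if query <= 0:
        raise InputError("query length must be positive")
    arr = np.asarray(lengths)
    percentile = float(np.mean(arr < query))
    top_fraction = float(np.mean(arr >= query))
    return percentile, top_fraction
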