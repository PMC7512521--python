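"""Suffix-order index answering multiplicity and repeat queries exactly.

The structure is a plain suffix array plus the LCP (longest-common-prefix)
array of adjacent suffixes in sorted order.  Together they answer every query
the informational indexes need:

* the longest repeated substring length is ``max(lcp)``;
* the shortest unique substring starting at position ``i`` extends one symbol
  past the longer of the LCPs with the two order-neighbours of suffix ``i``;
* distinct/hapax/repeat k-mer counts fall out of runs of ``lcp >= k``.

The suffix array is built by prefix doubling with numpy's radix ``lexsort``
(O(n log² n), fully vectorised), which handles the 10⁷-symbol strings the
largest analyses need in well under a minute; the LCP array uses Kasai's
linear-time algorithm, JIT-compiled.  Exactness is anchored by the naive
oracle in :mod:`logbounds.naive`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .symbols import SymbolString

__all__ = ["SuffixIndex", "build_index", "suffix_array", "lcp_array"]


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling.

    Returns the permutation ``sa`` of ``[0, n)`` with suffixes in increasing
    lexicographic order (a shorter suffix precedes its extensions).
    """
    codes = np.ascontiguousarray(codes, dtype=np.int64)
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while True:
        # sort by (rank[i], rank[i+k]), absent second key ranks lowest
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        tmp[sa[0]] = 0
        prev, cur = sa[:-1], sa[1:]
        changed = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        tmp[cur] = np.cumsum(changed)
        rank = tmp.copy()
        if rank[sa[-1]] == n - 1:  # all ranks distinct: fully sorted
            return sa
        k *= 2


@njit(cache=True)
def _kasai(codes, sa):  # pragma: no cover - exercised via lcp_array
    n = sa.size
    rank = np.empty(n, np.int64)
    for i in range(n):
        rank[sa[i]] = i
    lcp = np.zeros(max(n - 1, 0), np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r - 1] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP of adjacent suffixes in suffix-array order (Kasai's algorithm).

    ``lcp[i]`` is the longest common prefix of suffixes ``sa[i]`` and
    ``sa[i+1]``; an empty array for n = 1.
    """
    codes = np.ascontiguousarray(codes, dtype=np.int64)
    return _kasai(codes, np.ascontiguousarray(sa, dtype=np.int64))


@dataclass(frozen=True)
class SuffixIndex:
    """Suffix order + adjacent-LCP structure over a :class:`SymbolString`."""

    string: SymbolString
    suffix_order: np.ndarray
    common_prefix_lengths: np.ndarray

    @property
    def n(self) -> int:
        return self.string.n

    @property
    def m(self) -> int:
        return self.string.m

    def neighbour_lcp(self) -> np.ndarray:
        """Per suffix-order position, the larger LCP with its two neighbours.

        Entry ``r`` refers to the suffix at ``suffix_order[r]``; boundary
        positions have a single neighbour.  One symbol past this value is the
        shortest prefix distinguishing the suffix from every other suffix.
        """
        n = self.n
        best = np.zeros(n, dtype=np.int64)
        if n > 1:
            lcp = self.common_prefix_lengths
            best[1:] = lcp
            np.maximum(best[:-1], lcp, out=best[:-1])
        return best


def build_index(s: SymbolString) -> SuffixIndex:
    """Build the suffix array and LCP array for a symbol string."""
    sa = suffix_array(s.codes)
    lcp = lcp_array(s.codes, sa)
    return SuffixIndex(s, sa, lcp)
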