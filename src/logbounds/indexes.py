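"""Informational indexes of a finite string.

For a string α of length n over an m-symbol alphabet, the vocabulary D_k(α)
is the set of distinct length-k substrings (k-mers).  A k-mer is a *repeat*
if it occurs more than once (overlapping occurrences count) and a *hapax* if
it occurs exactly once.  The indexes computed here:

* ``mrl`` — maximum repeat length: length of the longest repeated substring
  (0 when no substring repeats);
* ``mhl`` — minimum hapax length: length of the shortest substring occurring
  exactly once (always defined: the whole string is a hapax);
* ``mcl`` — maximum complete length: largest k such that *all* m^k possible
  k-mers occur (0 if some declared symbol never occurs);
* per-k statistics — distinct/hapax/repeat counts and the empirical
  k-entropy E_k = −Σ p(w) log_m p(w) with p(w) = mult(w)/(n−k+1).

Everything is derived from the suffix array + LCP structure of
:mod:`logbounds.suffix`; the naive counterparts in :mod:`logbounds.naive`
serve as the correctness oracle.

Useful facts (all checked as test invariants): substrings of repeats are
repeats, superstrings of hapaxes are hapaxes; hence for k > mrl every k-mer
is a hapax and for k < mhl every k-mer is a repeat; mhl ≥ mcl; |D_k| ≤
min(m^k, n−k+1); mcl ≤ ⌈log_m n⌉; E_k attains its maximum log_m(n−k+1)
exactly when every k-mer is a hapax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .suffix import SuffixIndex, build_index
from .symbols import SymbolString

__all__ = [
    "KmerStats",
    "IndexProfile",
    "multiplicity",
    "max_repeat_length",
    "min_hapax_length",
    "max_complete_length",
    "kmer_stats",
    "profile",
]


@dataclass(frozen=True)
class KmerStats:
    """Vocabulary statistics of the k-mers of a string."""

    k: int
    distinct_count: int
    hapax_count: int
    repeat_count: int
    entropy: float
    complete: bool

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "distinct": self.distinct_count,
            "hapax": self.hapax_count,
            "repeat": self.repeat_count,
            "entropy": self.entropy,
            "complete": self.complete,
        }


@dataclass(frozen=True)
class IndexProfile:
    """The informational indexes of one string: mrl, mhl, mcl and per-k stats."""

    n: int
    m: int
    mrl: int
    mhl: int
    mcl: int
    per_k: tuple[KmerStats, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "mrl": self.mrl,
            "mhl": self.mhl,
            "mcl": self.mcl,
            "per_k": [s.to_dict() for s in self.per_k],
        }


def _require_log_alphabet(m: int) -> None:
    if m < 2:
        raise ValueError("degenerate alphabet: logarithmic indexes need m >= 2")


def multiplicity(idx: SuffixIndex, word: "str | Sequence[int] | np.ndarray") -> int:
    """Number of (possibly overlapping) occurrences of ``word`` in the string.

    Binary search over the suffix order: occurrences of a word form a
    contiguous rank interval, located in O(|word| · log n).
    """
    w = idx.string.encode_word(word)
    if w.size == 0:
        raise ValueError("empty query")
    n, codes, sa = idx.n, idx.string.codes, idx.suffix_order
    if w.size > n or (w < 0).any() or (w >= idx.m).any():
        return 0

    def cmp_suffix(pos: int) -> int:
        """-1/0/+1 comparing suffix at pos against w on the first |w| symbols."""
        chunk = codes[pos : pos + w.size]
        ww = w[: chunk.size]
        diff = chunk != ww
        hit = np.argmax(diff) if diff.any() else -1
        if hit >= 0:
            return -1 if chunk[hit] < ww[hit] else 1
        return -1 if chunk.size < w.size else 0  # short suffix sorts before

    lo, hi = 0, n  # lower bound: first suffix with prefix >= w
    while lo < hi:
        mid = (lo + hi) // 2
        if cmp_suffix(int(sa[mid])) < 0:
            lo = mid + 1
        else:
            hi = mid
    first = lo
    hi = n  # upper bound: first suffix with prefix > w
    while lo < hi:
        mid = (lo + hi) // 2
        if cmp_suffix(int(sa[mid])) <= 0:
            lo = mid + 1
        else:
            hi = mid
    return lo - first


def max_repeat_length(idx: SuffixIndex) -> int:
    """Length of the longest repeated substring (mrl); 0 if none repeats.

    A repeated substring of maximal length is a common prefix of two
    suffixes, and the pair can be taken adjacent in suffix order, so mrl is
    the maximum adjacent LCP.
    """
    lcp = idx.common_prefix_lengths
    return int(lcp.max()) if lcp.size else 0


def min_hapax_length(idx: SuffixIndex) -> int:
    """Length of the shortest substring occurring exactly once (mhl).

    The shortest hapax starting at position i is one symbol longer than the
    larger LCP of suffix i with its suffix-order neighbours, provided that
    witness still fits before the string end; mhl minimises over i.  The
    whole string always qualifies, so 1 ≤ mhl ≤ n.
    """
    n = idx.n
    cand = idx.neighbour_lcp() + 1
    fits = idx.suffix_order + cand <= n
    return int(cand[fits].min())


def _distinct_counts(idx: SuffixIndex, ks: np.ndarray) -> np.ndarray:
    """|D_k| for each requested k, via the LCP histogram.

    Two suffixes share a k-prefix iff their suffix-order interval has all
    adjacent LCPs ≥ k, and no shorter suffix can separate them, so
    |D_k| = (n−k+1) − #{adjacent pairs with lcp ≥ k}.
    """
    n = idx.n
    lcp = idx.common_prefix_lengths
    if lcp.size:
        hist = np.bincount(np.minimum(lcp, n))
        ge = np.concatenate([np.cumsum(hist[::-1])[::-1], [0]])  # ge[k] = #{lcp >= k}
    else:
        ge = np.zeros(n + 2, dtype=np.int64)
    ks = np.asarray(ks)
    out = (n - ks + 1) - np.where(ks < ge.size, ge[np.minimum(ks, ge.size - 1)], 0)
    return out.astype(np.int64)


def kmer_stats(idx: SuffixIndex, k: int) -> KmerStats:
    """Distinct/hapax/repeat counts and empirical k-entropy for one k."""
    n, m = idx.n, idx.m
    if not 1 <= k <= n:
        raise ValueError("invalid k")
    _require_log_alphabet(m)
    lcp = idx.common_prefix_lengths
    sa = idx.suffix_order
    kept = sa <= n - k  # suffixes long enough to carry a k-mer
    # group suffixes by shared k-prefix: runs of adjacent lcp >= k
    if lcp.size:
        gid = np.concatenate([[0], np.cumsum(lcp < k)])
    else:
        gid = np.zeros(n, dtype=np.int64)
    counts = np.bincount(gid[kept])
    counts = counts[counts > 0]
    distinct = int(counts.size)
    hapax = int((counts == 1).sum())
    total = n - k + 1
    p = counts / total
    entropy = float(-(p * np.log(p)).sum() / math.log(m))
    complete = distinct == m**k
    return KmerStats(k, distinct, hapax, distinct - hapax, entropy, complete)


def max_complete_length(idx: SuffixIndex) -> int:
    """Largest k with all m^k possible k-mers present (mcl).

    0 when some declared symbol never occurs.  The search stops at
    k = ⌈log_m n⌉, the proven upper bound (m^k ≤ n − k + 1 is necessary).
    """
    n, m = idx.n, idx.m
    _require_log_alphabet(m)
    kmax = _ceil_log(n, m)
    ks = np.arange(1, max(kmax, 1) + 1)
    distinct = _distinct_counts(idx, ks)
    mcl = 0
    needed = 1
    for k, d in zip(ks, distinct):
        needed *= m
        if needed > n - int(k) + 1 or int(d) != needed:
            break
        mcl = int(k)
    return mcl


def _ceil_log(n: int, m: int) -> int:
    """⌈log_m n⌉ by exact integer arithmetic (no float drift at n = m^j)."""
    j, power = 0, 1
    while power < n:
        power *= m
        j += 1
    return j


def profile(s: SymbolString, k_values: Sequence[int] | None = None) -> IndexProfile:
    """Compute mrl, mhl, mcl and per-k statistics in one pass.

    ``k_values`` defaults to 1 .. mrl+1 (capped at n), covering the whole
    repeat spectrum: beyond mrl+1 every k-mer is a hapax and the statistics
    change only trivially.
    """
    idx = build_index(s)
    mrl = max_repeat_length(idx)
    mhl = min_hapax_length(idx)
    mcl = max_complete_length(idx)
    if k_values is None:
        k_values = range(1, min(mrl + 1, s.n) + 1)
    per_k = tuple(kmer_stats(idx, int(k)) for k in k_values)
    return IndexProfile(s.n, s.m, mrl, mhl, mcl, per_k)
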