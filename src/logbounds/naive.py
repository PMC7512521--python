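"""Brute-force reference implementations of every informational index.

These are the definitional oracles: substrings are enumerated and counted in
dictionaries, with no suffix structure anywhere.  They are quadratic-ish and
meant for strings up to a few thousand symbols — the self-test
(:func:`selftest`) compares them against the production suffix-array path on
random inputs, which is what anchors the exactness claims of
:mod:`logbounds.indexes`.

The only shortcut taken: the upward scan over k stops at the first k with no
repeated k-mer, because the length-k prefix of a repeated (k+1)-mer is itself
repeated — so repeats vanish for good once they vanish.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "naive_multiplicity",
    "naive_kmer_counts",
    "naive_mrl",
    "naive_mhl",
    "naive_mcl",
    "naive_entropy",
    "naive_suffix_order",
    "selftest",
    "SelfTestResult",
]


def _as_tuple(codes) -> tuple:
    return tuple(int(c) for c in np.asarray(codes).ravel())


def naive_multiplicity(codes, word) -> int:
    """Count overlapping occurrences by sliding the word over the string."""
    s, w = _as_tuple(codes), _as_tuple(word)
    if not w:
        raise ValueError("empty query")
    return sum(1 for i in range(len(s) - len(w) + 1) if s[i : i + len(w)] == w)


def naive_kmer_counts(codes, k: int) -> Counter:
    """Occurrence counts of every distinct k-mer."""
    s = _as_tuple(codes)
    if not 1 <= k <= len(s):
        raise ValueError("invalid k")
    return Counter(s[i : i + k] for i in range(len(s) - k + 1))


def naive_mrl(codes) -> int:
    """Longest repeated substring length, scanning k upward."""
    n = len(codes)
    mrl = 0
    for k in range(1, n + 1):
        counts = naive_kmer_counts(codes, k)
        if max(counts.values()) <= 1:
            break
        mrl = k
    return mrl


def naive_mhl(codes) -> int:
    """Shortest hapax length: first k whose vocabulary contains a singleton."""
    n = len(codes)
    for k in range(1, n + 1):
        if 1 in naive_kmer_counts(codes, k).values():
            return k
    return n  # unreachable: the whole string is a hapax


def naive_mcl(codes, m: int) -> int:
    """Largest k with all m^k k-mers present, by direct enumeration."""
    n = len(codes)
    mcl = 0
    for k in range(1, n + 1):
        if m**k > n - k + 1 or len(naive_kmer_counts(codes, k)) != m**k:
            break
        mcl = k
    return mcl


def naive_entropy(codes, k: int, m: int) -> float:
    """Empirical k-entropy −Σ p log_m p with p = mult/(n−k+1)."""
    counts = naive_kmer_counts(codes, k)
    total = len(codes) - k + 1
    return -sum((c / total) * math.log(c / total, m) for c in counts.values())


def naive_suffix_order(codes) -> list[int]:
    """Start positions sorted by direct lexicographic suffix comparison."""
    s = _as_tuple(codes)
    return sorted(range(len(s)), key=lambda i: s[i:])


@dataclass
class SelfTestResult:
    trials: int
    failures: list[str]

    @property
    def ok(self) -> bool:
        return not self.failures


def selftest(trials: int = 50, seed: int = 0, max_n: int = 300) -> SelfTestResult:
    """Compare the suffix-array path against the oracles on random strings.

    Draws strings with n ≤ ``max_n`` over alphabets m ∈ {2, 4, 10, 26} and
    checks mrl, mhl, mcl, sampled multiplicities and per-k statistics for
    exact agreement.  Used by ``lbt selftest`` and by the test suite.
    """
    from . import indexes
    from .suffix import build_index
    from .symbols import from_codes

    rng = np.random.default_rng(seed)
    failures: list[str] = []
    for t in range(trials):
        m = int(rng.choice([2, 4, 10, 26]))
        n = int(rng.integers(2, max_n + 1))
        codes = rng.integers(0, m, n)
        s = from_codes(codes, m)
        idx = build_index(s)

        def check(tag, got, want):
            if got != want:
                failures.append(f"trial {t} (n={n}, m={m}) {tag}: got {got}, want {want}")

        check("mrl", indexes.max_repeat_length(idx), naive_mrl(codes))
        check("mhl", indexes.min_hapax_length(idx), naive_mhl(codes))
        check("mcl", indexes.max_complete_length(idx), naive_mcl(codes, m))
        check("suffix_order", list(idx.suffix_order), naive_suffix_order(codes))
        for _ in range(3):
            k = int(rng.integers(1, min(n, 12) + 1))
            i = int(rng.integers(0, n - k + 1))
            word = codes[i : i + k]
            check(
                f"multiplicity(k={k})",
                indexes.multiplicity(idx, word),
                naive_multiplicity(codes, word),
            )
            st = indexes.kmer_stats(idx, k)
            counts = naive_kmer_counts(codes, k)
            check(f"distinct(k={k})", st.distinct_count, len(counts))
            check(
                f"hapax(k={k})",
                st.hapax_count,
                sum(1 for c in counts.values() if c == 1),
            )
            if abs(st.entropy - naive_entropy(codes, k, m)) > 1e-9:
                failures.append(f"trial {t} entropy(k={k}) mismatch")
    return SelfTestResult(trials, failures)
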