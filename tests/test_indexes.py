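import math

import numpy as np
import pytest

from logbounds import (
    build_index,
    encode,
    from_codes,
    kmer_stats,
    max_complete_length,
    max_repeat_length,
    min_hapax_length,
    multiplicity,
    profile,
    uniform_string,
)
from logbounds.indexes import _ceil_log
from logbounds.naive import (
    naive_kmer_counts,
    naive_mhl,
    naive_mrl,
    naive_multiplicity,
)


@pytest.mark.parametrize(
    "text,alphabet,mrl,mhl,mcl",
    [
        ("banana", "abn", 3, 1, 1),  # longest repeat "ana", hapax "b"
        ("abcd", None, 0, 1, 1),  # all symbols distinct
        ("aabb", "ab", 1, 2, 1),  # no 1-mer hapax; "aa" unique
        ("aaaa", "ab", 3, 4, 0),  # b never occurs
        ("aab", "abc", 1, 1, 0),  # declared symbol c absent
    ],
)
def test_index_triples_on_hand_built_strings(text, alphabet, mrl, mhl, mcl):
    idx = build_index(encode(text, alphabet=alphabet))
    assert max_repeat_length(idx) == mrl
    assert min_hapax_length(idx) == mhl
    assert max_complete_length(idx) == mcl


@pytest.mark.parametrize(
    "text,word,count",
    [
        ("banana", "ana", 2),  # overlapping occurrences both counted
        ("aaaaa", "aa", 4),
        ("banana", "z", 0),
        ("banana", "banana", 1),
        ("banana", "nanan", 0),
    ],
)
def test_multiplicity_counts_overlaps(text, word, count):
    idx = build_index(encode(text))
    assert multiplicity(idx, word) == count


def test_multiplicity_rejects_empty_query():
    idx = build_index(encode("abc"))
    with pytest.raises(ValueError, match="empty query"):
        multiplicity(idx, "")


def test_kmer_stats_examples():
    idx = build_index(encode("aaaa", alphabet="ab"))
    st1 = kmer_stats(idx, 1)
    assert st1.distinct_count == 1 and st1.entropy == pytest.approx(0.0)
    assert st1.repeat_count == 1 and st1.hapax_count == 0

    idx = build_index(encode("abab"))
    st1 = kmer_stats(idx, 1)  # p(a)=p(b)=1/2, base-2 log
    assert st1.entropy == pytest.approx(1.0)

    idx = build_index(encode("abcd"))  # every 2-mer a hapax
    st2 = kmer_stats(idx, 2)
    assert st2.hapax_count == st2.distinct_count == 3
    assert st2.entropy == pytest.approx(math.log(3, 4))


def test_kmer_stats_invalid_k():
    idx = build_index(encode("abc"))
    for k in (0, 4):
        with pytest.raises(ValueError, match="invalid k"):
            kmer_stats(idx, k)


def test_profile_aggregates():
    p = profile(encode("banana", alphabet="abn"))
    assert (p.mrl, p.mhl, p.mcl) == (3, 1, 1)
    assert [s.k for s in p.per_k] == [1, 2, 3, 4]  # default 1..mrl+1
    p = profile(encode("abcd"))
    assert (p.mrl, p.mhl, p.mcl) == (0, 1, 1)
    q = profile(encode("banana", alphabet="abn"), k_values=[2])
    assert len(q.per_k) == 1 and q.per_k[0].k == 2
    d = p.to_dict()
    assert d["mrl"] == 0 and len(d["per_k"]) == 1


def test_degenerate_alphabet_rejected_for_log_indexes():
    idx = build_index(from_codes([0, 0, 0], 1))
    assert max_repeat_length(idx) == 2  # counting still works
    with pytest.raises(ValueError, match="degenerate"):
        max_complete_length(idx)
    with pytest.raises(ValueError, match="degenerate"):
        kmer_stats(idx, 1)


# ---------------------------------------------------------------------------
# the structural propositions, as invariant suites over assorted strings


def test_beyond_mrl_all_kmers_are_hapaxes(assorted_strings):
    for s in assorted_strings:
        idx = build_index(s)
        mrl = max_repeat_length(idx)
        for k in range(mrl + 1, min(mrl + 4, s.n) + 1):
            st = kmer_stats(idx, k)
            assert st.hapax_count == st.distinct_count, f"k={k} on n={s.n}"


def test_below_mhl_all_kmers_are_repeats(assorted_strings):
    for s in assorted_strings:
        idx = build_index(s)
        mhl = min_hapax_length(idx)
        for k in range(1, mhl):
            assert kmer_stats(idx, k).hapax_count == 0


def test_mhl_at_least_mcl(assorted_strings):
    for s in assorted_strings:
        idx = build_index(s)
        assert min_hapax_length(idx) >= max_complete_length(idx)


def test_distinct_count_bounds_and_all_hapax_case(assorted_strings):
    for s in assorted_strings:
        idx = build_index(s)
        for k in (1, 2, max(1, s.n // 2), s.n):
            st = kmer_stats(idx, k)
            assert st.distinct_count <= min(s.m**k, s.n - k + 1)
            assert st.distinct_count == st.hapax_count + st.repeat_count
            if st.distinct_count == s.n - k + 1:
                assert st.hapax_count == st.distinct_count


def test_mcl_bounded_by_ceil_log(assorted_strings):
    for s in assorted_strings:
        idx = build_index(s)
        assert max_complete_length(idx) <= _ceil_log(s.n, s.m)


def test_entropy_maximal_iff_all_hapax(assorted_strings):
    for s in assorted_strings:
        idx = build_index(s)
        mrl = max_repeat_length(idx)
        k = min(mrl + 1, s.n)
        st = kmer_stats(idx, k)
        if st.hapax_count == st.distinct_count == s.n - k + 1:
            assert st.entropy == pytest.approx(math.log(s.n - k + 1, s.m), abs=1e-9)
        assert 0.0 <= st.entropy <= math.log(s.n - k + 1, s.m) + 1e-9


def test_repeat_substrings_and_hapax_superstrings(assorted_strings):
    """Every substring of a repeat is a repeat; every in-string superstring
    of a hapax is a hapax (checked on sampled words)."""
    rng = np.random.default_rng(5)
    for s in assorted_strings[:6]:
        idx = build_index(s)
        codes = s.codes
        for _ in range(10):
            k = int(rng.integers(1, min(8, s.n) + 1))
            i = int(rng.integers(0, s.n - k + 1))
            word = codes[i : i + k]
            mult = multiplicity(idx, word)
            if mult > 1 and k > 1:  # substrings of a repeat repeat
                assert multiplicity(idx, word[:-1]) > 1
                assert multiplicity(idx, word[1:]) > 1
            if mult == 1 and i + k < s.n:  # extending a hapax keeps it hapax
                assert multiplicity(idx, codes[i : i + k + 1]) == 1


def test_suffix_path_matches_oracle_on_random_strings():
    rng = np.random.default_rng(99)
    for _ in range(25):
        m = int(rng.choice([2, 4, 10, 26]))
        n = int(rng.integers(2, 400))
        codes = rng.integers(0, m, n)
        idx = build_index(from_codes(codes, m))
        assert max_repeat_length(idx) == naive_mrl(codes)
        assert min_hapax_length(idx) == naive_mhl(codes)
        k = int(rng.integers(1, min(n, 10) + 1))
        st = kmer_stats(idx, k)
        counts = naive_kmer_counts(codes, k)
        assert st.distinct_count == len(counts)
        i = int(rng.integers(0, n - k + 1))
        assert multiplicity(idx, codes[i : i + k]) == naive_multiplicity(
            codes, codes[i : i + k]
        )


def test_mhl_of_uniform_string_defined_and_positive():
    s = uniform_string(4, 3000, 11)
    idx = build_index(s)
    mhl = min_hapax_length(idx)
    assert 1 <= mhl <= s.n
    assert 0 <= max_repeat_length(idx) < s.n
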