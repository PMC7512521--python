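# Methods

## Model

A finite string α over an *m*-symbol alphabet is treated as an information
source; its internal structure is summarised by the multiplicity function
mult_α(w) (occurrences of *w* in α, overlaps counted — required for the
occurrence probabilities p(w) = mult_α(w)/(n−k+1) to sum to one over
D_k(α)). The derived indexes are

* mrl = max{k : some k-mer has multiplicity > 1} (0 when all substrings are
  unique — the maximum over an empty set is defined as 0),
* mhl = min{k : some k-mer has multiplicity 1} (always defined: the whole
  string occurs once, so 1 ≤ mhl ≤ n),
* mcl = max{k : |D_k(α)| = m^k} (0 when a declared symbol never occurs),
* E_k = −Σ p(w) log_m p(w), the empirical k-entropy in base-m units.

Structural facts used throughout (and asserted as test invariants): every
substring of a repeat is a repeat and every in-string superstring of a
hapax is a hapax; hence all k-mers repeat for k < mhl and all are hapaxes
for k > mrl; mhl ≥ mcl; |D_k| ≤ min(m^k, n−k+1), with every k-mer a hapax
at equality with n−k+1; mcl ≤ ⌈log_m n⌉; E_k is maximal, log_m(n−k+1),
exactly when every k-mer is a hapax.

For an idealised random source (each k-mer equally likely at each position,
with the a-posteriori occurrence probability equal to the a-priori one) the
repeat spectrum collapses onto two bounds: mhl ≤ ⌈LG⌉ and mrl+1 = ⌈2LG⌉,
where LG = log_m n. The heuristic is the birthday bound: ~n²/2 substring
pairs can collide, and a k-mer match has probability m^(−k), so repeats die
out at k ≈ 2 log_m n, while a specific k-mer stops recurring once m^k
outgrows n at k ≈ log_m n.

## The test

The Log Bounds Test evaluates a string's prefixes at the half-decade
schedule {10^j, 2·10^j, 5·10^j} ∩ [10, n] ∪ {n} (user-overridable). Each
prefix is indexed from scratch — simplicity and exactness over an
incremental scheme; the total cost is dominated by the last prefix anyway —
and scored:

* mhl check: |mhl − ⌈LG⌉| ≤ 1;
* mrl check: |(mrl+1) − ⌈2LG⌉| ≤ 1.

The report carries one row per prefix, the fraction of rows passing both
checks (score), and the mean and population standard deviation of the
signed deviations mhl − ⌈LG⌉ and (mrl+1) − ⌈2LG⌉ across rows ("average
behaviour with spread"; the aggregate is deliberately simple — the test
defines no p-value and none is offered).

Ceilings are computed in exact integer arithmetic (smallest j with
m^j ≥ n, resp. m^j ≥ n²), so n = m^j never drifts across the ceiling; the
standard mathematical ceiling is used (⌈x⌉ = x for integer x). ⌈2LG⌉ is
the ceiling of 2·log_m n, not 2·⌈LG⌉ — the two differ at half-decade
lengths (e.g. n = 2·10⁴, m = 10: ⌈8.602⌉ = 9 vs 10); published tabulations
of this statistic are not consistent about the convention, and this package
fixes the former as the faithful reading of the formula.

The ±1 tolerance is symmetric by construction. For genuinely random
sources the mrl check's true pass probability at moderate n is about
90–95%, not 1 — e.g. for m = 4, n = 10⁵ the window {16,17,18} for mrl+1
captures ≈92% of uniform strings (P(mrl+1 < 16) ≈ exp(−(n²/2)·4⁻¹⁵) ≈ 1%,
P(mrl+1 > 18) ≈ 1 − exp(−(n²/2)·4⁻¹⁸) ≈ 7%) — a single ✗ row in a long
scan is therefore not evidence of non-randomness; structured sources fail
by tens of symbols, not one.

## Algorithms

The engine is a suffix array with the LCP array of adjacent sorted
suffixes:

* construction by prefix doubling over numpy's radix `lexsort`,
  O(n log² n) fully vectorised (~25 s at n = 10⁷, the largest size the
  built-in analyses use); LCP by Kasai's O(n) algorithm, numba-compiled;
* mrl = max adjacent LCP (a maximal repeat is a common prefix of two
  suffixes adjacent in sorted order);
* mhl: the shortest hapax starting at position i has length one more than
  the larger LCP of suffix i with its two order-neighbours, provided that
  witness fits before the string end; minimise over i;
* |D_k| = (n−k+1) − #{adjacent LCP ≥ k}: suffixes sharing a k-prefix are
  contiguous in suffix order (a shorter suffix cannot sort strictly between
  two of them, since it would have to be a proper prefix of the shared
  k-prefix and would then sort before both), so each size-c class
  contributes c−1 adjacent pairs with LCP ≥ k;
* per-k multiplicity classes (for hapax/repeat counts and E_k) are the
  maximal runs of adjacent LCP ≥ k, restricted to suffixes of length ≥ k;
* word multiplicity by binary search for the word's rank interval,
  O(|w| log n);
* mcl scans k up to the proven bound ⌈log_m n⌉ using the |D_k| formula.

Suffix structure over hashing so that mrl/mhl are exact rather than
probabilistic. A brute-force oracle (dictionary counting over enumerated
substrings, direct suffix sorting — no suffix structure anywhere) lives in
`logbounds.naive`; `lbt selftest` and the test suite compare the two paths
for exact agreement on hundreds of random strings up to n = 2000 over
m ∈ {2, 4, 10, 26}. Entropy comparisons use an absolute tolerance of 1e-9;
all other quantities are integers and compared exactly.

The alphabet size m entering logarithms and m^k is the *declared* size,
defaulting to the observed distinct-symbol count; readers and the CLI can
override it (nominal sizes — 10 digits, 26 letters, 4 nucleotides, 256
bytes — are what published analyses use, and an absent declared symbol
legitimately forces mcl = 0). m = 1 is rejected for any logarithmic index
(log base 1), while plain counting still works.

## Generators

* **π, e, √2 digits** — mpmath at a working precision of n + 20 digits
  (integer-part digit included, decimal point removed). The emitted prefix
  is re-computed at doubled guard precision whenever the digits just past
  position n are a solid run of 9s or 0s, the only case where rounding
  could disturb an emitted digit; every digit is therefore exact. Dropping
  or keeping the integer-part digit does not move mrl/mhl at the scales
  analysed (the witnesses are interior substrings; checked in tests via
  prefix-stability plus the reference values).
* **Champernowne** — "123456789101112…", concatenation by counting.
* **Logistic map** — x_{i+1} = r·x_i(1−x_i) iterated in IEEE double
  precision from x₀; symbol floor(m·x_i) (clipped to m−1), *emitted from x₀
  itself*. The emission offset and binning are conventions; a chaotic orbit
  (r near 4) is exponentially sensitive to them and to platform rounding,
  so small-index values (notably mhl) can differ between otherwise
  reasonable implementations even when the repeat structure (mrl) agrees.
  A degenerate orbit hitting 0 or 1 warns and continues.
* **LCG** — x_{i+1} = (c·x_i + b) mod M in exact integer arithmetic
  (the Java preset c = 25214903917, b = 11, M = 2⁴⁸ overflows 64-bit
  products), symbol floor(m·x_{i+1}/M). The hapax length of its decimal
  stream at n = 10⁶ is seed-robust (identical across every seed tried),
  which is what the reference comparison relies on, since no specific seed
  is canonical.
* **Uniform** — i.i.d. symbols from numpy's seeded PCG64; the Bernoulli
  urn model. This is the null model the test is calibrated against: real
  "random" data (physical sources, shuffled corpora) carry correlations the
  generator does not emulate, so a test passing on uniform strings shows
  correct calibration of the bounds, not that any particular physical
  source is random.

All deterministic generators are prefix-stable: requesting more symbols
never alters already-emitted ones.

## Problem sizes

The bundled analyses use the sizes at which the reference values are
defined: digit expansions up to 10⁶ (π) and counters up to 10⁷
(Champernowne), congruential streams of 10⁶ over 10 seeds, and 50 uniform
replicates at 10⁵ for the stochastic calibration check. The full
acceptance recomputation runs in under a minute on one CPU; peak memory is
a few hundred MB at n = 10⁷ (several int64 arrays of length n).

## Limitations

* The suffix array is rebuilt per prefix; an incremental/streaming mode
  would be an optimisation only.
* No compressed indexes; memory is ~40 bytes/symbol during construction,
  practical to n ≈ 10⁸ on a 8 GB machine but not beyond.
* The test yields a score, not a significance level; it deliberately does
  not replace statistical batteries (NIST, Diehard) and measures only
  repeat-spectrum conformance.
* External corpora (quantum bytes, roulette spins, literary text, genomes)
  are supported through the plain-text/FASTA readers but are not bundled;
  analyses of those sources require the user to supply the files.
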