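"""Integer-coded finite-alphabet strings.

A :class:`SymbolString` is the package's in-memory representation of a finite
string over an alphabet of ``m`` symbols: a numpy array of integer codes in
``[0, m)`` plus a table mapping codes back to the original characters/tokens.
All index computations (repeat/hapax lengths, k-mer entropy) operate on the
codes; the table exists only for reporting and for encoding query words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SymbolString", "encode", "from_codes"]


@dataclass(frozen=True)
class SymbolString:
    """A finite string over an ``m``-symbol alphabet, stored as integer codes.

    Attributes
    ----------
    codes : numpy.ndarray of int64
        Symbol codes, each in ``[0, alphabet_size)``.
    alphabet_size : int
        Declared alphabet size ``m``.  May exceed the number of distinct
        codes present (a declared symbol that never occurs), which matters
        for the completeness index and the base of all logarithms.
    symbol_table : tuple of str
        ``symbol_table[code]`` is the original character/token for ``code``.
    """

    codes: np.ndarray
    alphabet_size: int
    symbol_table: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        codes = np.ascontiguousarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size == 0:
            raise ValueError("empty sequence")
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        lo, hi = int(codes.min()), int(codes.max())
        if lo < 0 or hi >= self.alphabet_size:
            raise ValueError(
                f"code out of range: codes span [{lo}, {hi}] but alphabet_size={self.alphabet_size}"
            )

    @property
    def n(self) -> int:
        """String length."""
        return int(self.codes.size)

    @property
    def m(self) -> int:
        """Declared alphabet size."""
        return int(self.alphabet_size)

    def __len__(self) -> int:
        return self.n

    def prefix(self, length: int) -> "SymbolString":
        """The prefix of the given length, sharing the alphabet."""
        if not 1 <= length <= self.n:
            raise ValueError("prefix exceeds string")
        return SymbolString(self.codes[:length], self.alphabet_size, self.symbol_table)

    def encode_word(self, word: "str | Sequence[int]") -> np.ndarray:
        """Encode a query word to codes using this string's symbol table.

        Accepts either a text word (looked up in the symbol table) or an
        already-coded integer sequence.  A character absent from the table is
        mapped to code -1 (it cannot occur in the string, so any query
        containing it has multiplicity zero).
        """
        if isinstance(word, str):
            table = {ch: i for i, ch in enumerate(self.symbol_table)}
            return np.array([table.get(ch, -1) for ch in word], dtype=np.int64)
        return np.asarray(list(word), dtype=np.int64)

    def to_text(self) -> str:
        """Decode back to text via the symbol table."""
        if len(self.symbol_table) < self.alphabet_size:
            raise ValueError("no complete symbol table attached")
        table = np.array(self.symbol_table, dtype=object)
        return "".join(table[self.codes])


def encode(text: Iterable[str], alphabet: Sequence[str] | None = None) -> SymbolString:
    """Encode a character sequence into a :class:`SymbolString`.

    With ``alphabet=None`` codes are assigned in first-appearance order and
    the alphabet size is the number of distinct characters.  With an explicit
    alphabet, codes follow the given order, ``m = len(alphabet)``, and a
    character outside it is an error.
    """
    chars = list(text)
    if not chars:
        raise ValueError("empty sequence")
    if alphabet is None:
        table: dict[str, int] = {}
        for ch in chars:
            if ch not in table:
                table[ch] = len(table)
    else:
        table = {ch: i for i, ch in enumerate(alphabet)}
        if len(table) != len(list(alphabet)):
            raise ValueError("duplicate symbol in declared alphabet")
        bad = next((ch for ch in chars if ch not in table), None)
        if bad is not None:
            raise ValueError(f"alphabet violation: {bad!r} not in declared alphabet")
    codes = np.fromiter((table[ch] for ch in chars), dtype=np.int64, count=len(chars))
    symbols = tuple(sorted(table, key=table.get))
    return SymbolString(codes, len(table), symbols)


def from_codes(
    codes: Sequence[int] | np.ndarray,
    alphabet_size: int,
    symbol_table: tuple[str, ...] | None = None,
) -> SymbolString:
    """Wrap pre-coded integers, with a default numeric symbol table.

    The default table maps code ``i`` to the decimal literal ``str(i)`` when
    ``m <= 10`` (so digit strings round-trip to text), otherwise to ``str(i)``
    tokens as well — callers needing single-character round-trips for large
    alphabets should pass their own table.
    """
    if symbol_table is None:
        symbol_table = tuple(str(i) for i in range(alphabet_size))
    return SymbolString(np.asarray(codes, dtype=np.int64), alphabet_size, symbol_table)
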