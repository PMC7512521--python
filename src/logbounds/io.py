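"""Readers and the analysis orchestrator.

Input preparation mirrors common corpus practice: a text is reduced to the
symbols of interest (digits for decimal expansions, case-folded letters for
natural language, A/C/G/T for genomes) and everything else is discarded —
silently but counted.  The declared alphabet size is nominal (10 digits, 26
letters, 4 nucleotides, 256 bytes), not the observed distinct-symbol count,
because the logarithmic bounds are defined against the alphabet the source
could emit.
"""

from __future__ import annotations

import logging
import string as _string
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .bounds import LBTReport, prefix_scan
from .symbols import SymbolString, encode

__all__ = ["InputDocument", "read_text", "read_fasta", "run_lbt"]

logger = logging.getLogger("logbounds")

_LETTERS = tuple(_string.ascii_lowercase)
_BYTES = tuple(chr(i) for i in range(256))
_DNA = tuple("ACGT")


@dataclass(frozen=True)
class InputDocument:
    """A prepared input: source, filter policy, and the derived string."""

    source: str
    filter_policy: str
    string: SymbolString
    dropped: int = 0

    @property
    def n(self) -> int:
        return self.string.n

    @property
    def m(self) -> int:
        return self.string.m


def _encode_filtered(
    kept: str, alphabet: tuple[str, ...], source: str, policy: str, dropped: int
) -> InputDocument:
    if not kept:
        raise ValueError("no symbols retained")
    if dropped:
        logger.info("%s: dropped %d characters outside filter %r", source, dropped, policy)
    return InputDocument(source, policy, encode(kept, alphabet), dropped)


def read_text(path: str | Path, filter: "str | Sequence[str]" = "none") -> InputDocument:
    """Read a plain-text/byte file into a symbol string.

    Filter policies: ``"none"`` keeps every byte (m = 256); ``"digits"``
    keeps ASCII digits (m = 10); ``"letters"`` keeps ASCII letters,
    case-folded (m = 26); any other iterable of characters is a custom
    alphabet in the given order, everything else dropped.
    """
    path = Path(path)
    raw = path.read_bytes().decode("latin-1")
    if isinstance(filter, str) and filter == "none":
        return _encode_filtered(raw, _BYTES, str(path), "none", 0)
    if isinstance(filter, str) and filter == "digits":
        kept = [c for c in raw if c.isdigit() and c.isascii()]
        return _encode_filtered(
            "".join(kept), tuple(_string.digits), str(path), "digits", len(raw) - len(kept)
        )
    if isinstance(filter, str) and filter == "letters":
        kept = [c.lower() for c in raw if c.isalpha() and c.isascii()]
        return _encode_filtered(
            "".join(kept), _LETTERS, str(path), "letters", len(raw) - len(kept)
        )
    custom = tuple(dict.fromkeys(filter))
    allowed = set(custom)
    kept = [c for c in raw if c in allowed]
    return _encode_filtered(
        "".join(kept), custom, str(path), "custom", len(raw) - len(kept)
    )


def read_fasta(
    path: str | Path, record: str | None = None, mode: str = "nucleotide"
) -> InputDocument:
    """Read FASTA into a symbol string (A/C/G/T, m = 4, for nucleotide mode).

    With ``record=None`` all records are concatenated in file order.
    Characters outside the nucleotide alphabet (N, IUPAC ambiguity codes,
    gaps) are dropped and the count logged.  ``mode="protein"`` keeps the 20
    standard amino-acid letters instead (m = 20).
    """
    path = Path(path)
    head = path.read_text().lstrip()
    if not head.startswith(">"):
        raise ValueError("invalid FASTA: missing '>' header")
    alphabet = _DNA if mode == "nucleotide" else tuple("ACDEFGHIKLMNPQRSTVWY")
    allowed = set(alphabet)
    chunks: list[str] = []
    total = 0
    found = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if record is not None and rec.id != record:
            continue
        found = True
        seq = str(rec.seq).upper()
        total += len(seq)
        chunks.append("".join(c for c in seq if c in allowed))
    if record is not None and not found:
        raise ValueError(f"record {record!r} not found in {path}")
    kept = "".join(chunks)
    return _encode_filtered(kept, alphabet, str(path), mode, total - len(kept))


def run_lbt(
    doc: InputDocument,
    prefixes: Sequence[int] | None = None,
    alphabet_size: int | None = None,
) -> LBTReport:
    """Run the Log Bounds Test on a prepared document.

    ``alphabet_size`` overrides the declared m (the tables for bytes,
    roulette, DNA and letters all use nominal sizes); it must cover every
    code present.  Per-prefix timing is logged at INFO level.
    """
    s = doc.string
    if alphabet_size is not None and alphabet_size != s.m:
        s = SymbolString(s.codes, alphabet_size, s.symbol_table)
    if prefixes is None:
        from .bounds import default_prefixes

        prefixes = default_prefixes(s.n)
    rows = []
    for p in sorted(int(x) for x in prefixes):
        t0 = time.perf_counter()
        sub = prefix_scan(s, [p])
        rows.append(sub.rows[0])
        logger.info("prefix n=%d indexed in %.2fs", p, time.perf_counter() - t0)
    return LBTReport(tuple(rows))
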