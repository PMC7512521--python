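"""The Log Bounds Test (LBT) for string randomness.

For a string of length n over m symbols define LG = log_m(n) and
2LG = 2·log_m(n).  For an ideal random string the two logarithmic bounds pin
down the repeat spectrum:

* every substring of length ≥ ⌈2LG⌉ is unrepeatable, and the longest repeat
  satisfies mrl + 1 = ⌈2LG⌉;
* some substring of length ⌈LG⌉ is already unique, i.e. mhl ≤ ⌈LG⌉.

The test therefore computes mhl and mrl+1 on a schedule of prefixes and
marks a prefix as random-looking when mhl falls within ±1 of ⌈LG⌉ and mrl+1
within ±1 of ⌈2LG⌉.  Deterministic sequences with hidden structure
(concatenated counters, chaotic orbits in finite precision, natural
language, genomes) blow past the 2LG bound with repeats far longer than a
random string could sustain, while good pseudo-random generators and digits
of π/e/√2 sit on the bounds almost exactly.

Ceilings are computed by exact integer arithmetic, so n = m^j never drifts
across the ceiling due to floating point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .indexes import max_repeat_length, min_hapax_length
from .suffix import build_index
from .symbols import SymbolString

__all__ = [
    "LogBounds",
    "LBTRow",
    "LBTReport",
    "bounds",
    "predicted_hapax_floor",
    "predicted_repeat_ceiling",
    "check_row",
    "prefix_scan",
    "default_prefixes",
    "report_to_tsv",
    "report_from_tsv",
    "report_to_json",
    "report_from_json",
]


def _ceil_log_pow(n_pow: int, m: int) -> int:
    """Smallest j ≥ 0 with m^j ≥ n_pow — i.e. ⌈log_m n_pow⌉, exactly."""
    j, power = 0, 1
    while power < n_pow:
        power *= m
        j += 1
    return j


@dataclass(frozen=True)
class LogBounds:
    """LG = log_m n, 2LG = 2·log_m n and their (exact) ceilings."""

    n: int
    m: int
    lg: float
    two_lg: float
    ceil_lg: int
    ceil_two_lg: int


def bounds(n: int, m: int) -> LogBounds:
    """Logarithmic and double-logarithmic length of an (n, m) string.

    ⌈2LG⌉ is computed as ⌈log_m n²⌉ in integers, which equals ⌈2·log_m n⌉.
    """
    if m < 2:
        raise ValueError("degenerate alphabet: m must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    lg = math.log(n, m)
    return LogBounds(n, m, lg, 2 * lg, _ceil_log_pow(n, m), _ceil_log_pow(n * n, m))


def predicted_hapax_floor(n: int, m: int) -> int:
    """⌈2LG⌉ — at or above this length all k-mers of a random string are
    hapaxes; equivalently mrl + 1 = ⌈2LG⌉ for random strings."""
    return bounds(n, m).ceil_two_lg


def predicted_repeat_ceiling(n: int, m: int) -> int:
    """⌈LG⌉ — the shortest hapax of a random string is no longer than this."""
    return bounds(n, m).ceil_lg


@dataclass(frozen=True)
class LBTRow:
    """One prefix of the scan: indexes vs bounds, with the two ±1 verdicts."""

    n: int
    mhl: int
    ceil_lg: int
    mhl_check: bool
    mrl_plus1: int
    ceil_two_lg: int
    mrl_check: bool

    @property
    def dev_mhl(self) -> int:
        return self.mhl - self.ceil_lg

    @property
    def dev_mrl(self) -> int:
        return self.mrl_plus1 - self.ceil_two_lg


def check_row(mhl: int, mrl: int, b: LogBounds) -> LBTRow:
    """Apply the ±1 coincidence rule to one prefix's indexes."""
    return LBTRow(
        n=b.n,
        mhl=mhl,
        ceil_lg=b.ceil_lg,
        mhl_check=abs(mhl - b.ceil_lg) <= 1,
        mrl_plus1=mrl + 1,
        ceil_two_lg=b.ceil_two_lg,
        mrl_check=abs(mrl + 1 - b.ceil_two_lg) <= 1,
    )


@dataclass(frozen=True)
class LBTReport:
    """Per-prefix rows plus the aggregate score and deviation statistics.

    ``score`` is the fraction of prefixes passing both checks; the deviation
    statistics are the mean and (population) standard deviation of the
    signed gaps mhl − ⌈LG⌉ and (mrl+1) − ⌈2LG⌉ across prefixes.
    """

    rows: tuple[LBTRow, ...]
    score: float = field(init=False)
    mean_dev_mhl: float = field(init=False)
    sd_dev_mhl: float = field(init=False)
    mean_dev_mrl: float = field(init=False)
    sd_dev_mrl: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("report needs at least one row")
        both = [r.mhl_check and r.mrl_check for r in self.rows]
        d1 = np.array([r.dev_mhl for r in self.rows], dtype=float)
        d2 = np.array([r.dev_mrl for r in self.rows], dtype=float)
        object.__setattr__(self, "score", float(np.mean(both)))
        object.__setattr__(self, "mean_dev_mhl", float(d1.mean()))
        object.__setattr__(self, "sd_dev_mhl", float(d1.std()))
        object.__setattr__(self, "mean_dev_mrl", float(d2.mean()))
        object.__setattr__(self, "sd_dev_mrl", float(d2.std()))


def default_prefixes(n: int) -> list[int]:
    """The decade/half-decade schedule {10^j, 2·10^j, 5·10^j} ∩ [10, n], plus n."""
    out = []
    base = 10
    while base <= n:
        for mult in (1, 2, 5):
            p = mult * base
            if 10 <= p <= n:
                out.append(p)
        base *= 10
    if n >= 10 and n not in out:
        out.append(n)
    if not out:
        out = [n]
    return sorted(out)


def prefix_scan(
    s: SymbolString, prefix_lengths: Sequence[int] | None = None
) -> LBTReport:
    """Run the Log Bounds Test on a schedule of prefixes of ``s``.

    Each prefix is indexed from scratch (suffix array + LCP), its mhl and
    mrl compared against ⌈LG⌉ and ⌈2LG⌉ for that prefix length, and the
    verdicts aggregated.  Default schedule: :func:`default_prefixes`.
    """
    if prefix_lengths is None:
        prefix_lengths = default_prefixes(s.n)
    prefix_lengths = sorted(int(p) for p in prefix_lengths)
    if prefix_lengths and prefix_lengths[-1] > s.n:
        raise ValueError("prefix exceeds string")
    rows = []
    for p in prefix_lengths:
        idx = build_index(s.prefix(p))
        rows.append(
            check_row(min_hapax_length(idx), max_repeat_length(idx), bounds(p, s.m))
        )
    return LBTReport(tuple(rows))


# ---------------------------------------------------------------------------
# serialization — TSV mirrors the table layout (PASS/FAIL for ✓/✗), JSON adds
# the aggregate statistics

_TSV_HEADER = "n\tmhl\tceil_LG\tcheck1\tmrl_plus_1\tceil_2LG\tcheck2"


def _mark(flag: bool) -> str:
    return "PASS" if flag else "FAIL"


def report_to_tsv(report: LBTReport) -> str:
    lines = [_TSV_HEADER]
    for r in report.rows:
        lines.append(
            f"{r.n}\t{r.mhl}\t{r.ceil_lg}\t{_mark(r.mhl_check)}"
            f"\t{r.mrl_plus1}\t{r.ceil_two_lg}\t{_mark(r.mrl_check)}"
        )
    return "\n".join(lines) + "\n"


def report_from_tsv(text: str) -> LBTReport:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or lines[0].strip() != _TSV_HEADER:
        raise ValueError("malformed report header")
    rows = []
    for ln in lines[1:]:
        n, mhl, clg, c1, mrl1, c2lg, c2 = ln.split("\t")
        rows.append(
            LBTRow(
                int(n), int(mhl), int(clg), c1 == "PASS",
                int(mrl1), int(c2lg), c2 == "PASS",
            )
        )
    return LBTReport(tuple(rows))


def report_to_json(report: LBTReport) -> str:
    return json.dumps(
        {
            "rows": [
                {
                    "n": r.n,
                    "mhl": r.mhl,
                    "ceil_LG": r.ceil_lg,
                    "check1": _mark(r.mhl_check),
                    "mrl_plus_1": r.mrl_plus1,
                    "ceil_2LG": r.ceil_two_lg,
                    "check2": _mark(r.mrl_check),
                }
                for r in report.rows
            ],
            "score": report.score,
            "mean_dev_mhl": report.mean_dev_mhl,
            "sd_dev_mhl": report.sd_dev_mhl,
            "mean_dev_mrl": report.mean_dev_mrl,
            "sd_dev_mrl": report.sd_dev_mrl,
        },
        indent=2,
    )


def report_from_json(text: str) -> LBTReport:
    obj = json.loads(text)
    rows = tuple(
        LBTRow(
            r["n"], r["mhl"], r["ceil_LG"], r["check1"] == "PASS",
            r["mrl_plus_1"], r["ceil_2LG"], r["check2"] == "PASS",
        )
        for r in obj["rows"]
    )
    return LBTReport(rows)
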