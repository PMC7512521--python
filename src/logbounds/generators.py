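"""Built-in string families for randomness evaluation, generated offline.

Seven families, matching the sources commonly used to exercise randomness
tests:

* decimal digits of π, e and √2 (arbitrary-precision, every digit exact);
* Champernowne's constant — the natural numbers concatenated, "1234567891011…"
  (normal in base 10, yet riddled with long internal repeats);
* logistic-map orbits x_{i+1} = r·x_i(1−x_i) discretised to m symbols;
* linear congruential generators, with the Java preset
  x_{n+1} = (25214903917·x_n + 11) mod 2^48;
* i.i.d. uniform symbols (the Bernoulli/urn model).

All deterministic families are prefix-stable: requesting more symbols
extends, never alters, what was already emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import mpmath
import numpy as np

from .symbols import SymbolString, from_codes

__all__ = [
    "GeneratorSpec",
    "JAVA_LCG",
    "pi_digits",
    "e_digits",
    "sqrt2_digits",
    "champernowne_digits",
    "logistic_string",
    "lcg_string",
    "uniform_string",
    "generate",
]

_DIGITS = tuple("0123456789")


def _digit_symbolstring(digits: str) -> SymbolString:
    codes = np.frombuffer(digits.encode("ascii"), dtype=np.uint8).astype(np.int64)
    codes -= ord("0")
    return SymbolString(codes, 10, _DIGITS)


def _const_digits(make_value, n: int, guard: int = 20) -> str:
    """First n decimal digits of a constant ≥ 1 (integer part included,
    decimal point removed), exact by construction.

    Evaluates at n + guard digits of working precision and re-evaluates with
    a doubled guard whenever the digits just past position n are a solid run
    of 9s or 0s — the only situation in which rounding of the guard tail
    could disturb an emitted digit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    while True:
        with mpmath.workdps(n + guard):
            value = make_value()
            text = mpmath.nstr(
                value, n + guard - 10, strip_zeros=False
            ).replace(".", "")
        tail = text[n : n + 8]
        if n + 8 < len(text) and tail not in ("9" * len(tail), "0" * len(tail)):
            return text[:n]
        guard *= 2


def pi_digits(n: int) -> SymbolString:
    """First n decimal digits of π: "3141592653…" (m = 10)."""
    return _digit_symbolstring(_const_digits(lambda: mpmath.mp.pi, n))


def e_digits(n: int) -> SymbolString:
    """First n decimal digits of e: "2718281828…" (m = 10)."""
    return _digit_symbolstring(_const_digits(lambda: mpmath.mp.e, n))


def sqrt2_digits(n: int) -> SymbolString:
    """First n decimal digits of √2: "1414213562…" (m = 10)."""
    return _digit_symbolstring(_const_digits(lambda: mpmath.sqrt(2), n))


def champernowne_digits(n: int) -> SymbolString:
    """First n digits of Champernowne's constant "123456789101112…" (m = 10)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    parts: list[str] = []
    total = 0
    i = 1
    while total < n:
        t = str(i)
        parts.append(t)
        total += len(t)
        i += 1
    return _digit_symbolstring("".join(parts)[:n])


def logistic_string(x0: float, r: float, n: int, m: int) -> SymbolString:
    """Discretised logistic-map orbit, emitted from x_0 itself.

    Iterates x_{i+1} = r·x_i(1−x_i) in IEEE double precision and emits
    symbol floor(x_i · m), clipped to m−1, for i = 0 .. n−1.  The orbit of a
    chaotic parameter (r near 4) is exquisitely sensitive to the emission
    convention and to floating-point platform details; downstream index
    values at large n inherit that sensitivity.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    if not 0.0 < r <= 4.0:
        raise ValueError("r must lie in (0, 4]")
    if m < 2:
        raise ValueError("m must be >= 2")
    out = np.empty(n, dtype=np.int64)
    x = float(x0)
    degenerate = False
    for i in range(n):
        out[i] = min(int(x * m), m - 1) if x > 0 else 0
        x = r * x * (1.0 - x)
        if x <= 0.0 or x >= 1.0:
            degenerate = True
    if degenerate:
        warnings.warn("logistic orbit reached the interval boundary (degenerate)")
    return from_codes(out, m)


#: multiplier/increment/modulus of the Java linear congruential generator
JAVA_LCG = (25214903917, 11, 2**48)


def lcg_string(
    c: int, b: int, modulus: int, seed: int, n: int, m: int
) -> SymbolString:
    """Linear congruential stream x_{i+1} = (c·x_i + b) mod M, discretised.

    Emits floor(m · x_{i+1} / M) per step — n symbols, not including the
    seed state.  Exact integer arithmetic throughout (the Java preset's
    products exceed 64 bits).
    """
    if modulus < 2:
        raise ValueError("modulus must be >= 2")
    if m < 2:
        raise ValueError("m must be >= 2")
    out = np.empty(n, dtype=np.int64)
    x = seed % modulus
    for i in range(n):
        x = (c * x + b) % modulus
        out[i] = (m * x) // modulus
    return from_codes(out, m)


def uniform_string(m: int, n: int, seed: int) -> SymbolString:
    """i.i.d. uniform symbols over [0, m) from a seeded PCG64 generator."""
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)
    return from_codes(rng.integers(0, m, n), m)


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one generated string family."""

    kind: str
    length: int
    alphabet_size: int = 10
    params: dict = field(default_factory=dict)

    _KINDS = ("pi", "e", "sqrt2", "champernowne", "logistic", "lcg", "uniform")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")

    def generate(self) -> SymbolString:
        return generate(self)


def generate(spec: GeneratorSpec) -> SymbolString:
    """Materialise the string a :class:`GeneratorSpec` describes."""
    n, m, p = spec.length, spec.alphabet_size, spec.params
    if spec.kind == "pi":
        return pi_digits(n)
    if spec.kind == "e":
        return e_digits(n)
    if spec.kind == "sqrt2":
        return sqrt2_digits(n)
    if spec.kind == "champernowne":
        return champernowne_digits(n)
    if spec.kind == "logistic":
        return logistic_string(p.get("x0", 0.1), p.get("r", 4.0), n, m)
    if spec.kind == "lcg":
        c, b, modulus = p.get("c"), p.get("b"), p.get("modulus")
        if c is None or b is None or modulus is None:
            c, b, modulus = JAVA_LCG
        return lcg_string(c, b, modulus, p.get("seed", 1), n, m)
    if spec.kind == "uniform":
        return uniform_string(m, n, p.get("seed", 0))
    raise AssertionError("unreachable")
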