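"""Finite alphabets with single- or multi-character symbol tokens.

Sequences are internally lists of integer symbol indices; the
:class:`Alphabet` owns the bijection between tokens and indices.
Multi-character tokens (e.g. structural letters written as two-character
codes) are supported: raw strings are tokenized by longest match against
the declared token set.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DNA_SYMBOLS = ["A", "C", "G", "T"]
# the 20 proteinogenic amino acids, one-letter codes, alphabetical
PROTEIN_SYMBOLS = list("ACDEFGHIKLMNPQRSTVWY")


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite alphabet with a symbol <-> index bijection."""

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise AlphabetError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError("duplicate symbols in alphabet")
        if any(not s for s in self.symbols):
            raise AlphabetError("empty symbol token")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise AlphabetError(f"symbol {symbol!r} not in alphabet") from None

    def symbol(self, i: int) -> str:
        return self.symbols[i]

    def encode(self, tokens) -> list[int]:
        """Encode an iterable of symbol tokens to indices."""
        return [self.index(t) for t in tokens]

    def decode(self, indices) -> list[str]:
        return [self.symbols[i] for i in indices]

    def tokenize(self, text: str) -> list[int]:
        """Split a raw string into symbol indices by longest match.

        Raises :class:`AlphabetError` naming the offending offset when a
        position cannot be resolved.
        """
        by_len = sorted({len(s) for s in self.symbols}, reverse=True)
        out: list[int] = []
        i = 0
        n = len(text)
        while i < n:
            for k in by_len:
                tok = text[i : i + k]
                if len(tok) == k and tok in self._index:
                    out.append(self._index[tok])
                    i += k
                    break
            else:
                raise AlphabetError(
                    f"cannot tokenize text at offset {i}: {text[i:i+8]!r}"
                )
        return out


def make_alphabet(spec) -> Alphabet:
    """Build an alphabet from a name ('dna', 'protein') or a token list."""
    if isinstance(spec, Alphabet):
        return spec
    if isinstance(spec, str):
        name = spec.lower()
        if name == "dna":
            return Alphabet(tuple(DNA_SYMBOLS))
        if name == "protein":
            return Alphabet(tuple(PROTEIN_SYMBOLS))
        raise AlphabetError(f"unknown built-in alphabet {spec!r}")
    return Alphabet(tuple(spec))
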