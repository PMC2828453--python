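"""Pattern expressions: finite word sets and restricted regular expressions.

A pattern denotes a finite, non-empty set of non-empty words over a
declared alphabet.  Three input dialects are supported:

* ``words`` — an explicit list of words;
* ``prosite`` — the PROSITE signature syntax (``[..]`` allowed set,
  ``{..}`` forbidden set, ``x``/``.`` wildcard, ``(n)``/``(n,m)``
  bounded repetition, elements optionally separated by ``-``);
* ``iupac-dna`` — a DNA word with IUPAC degenerate codes.

Unbounded repetition and anchors are rejected: the occurrence-counting
machinery requires a finite language and unanchored semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

from .alphabet import Alphabet, AlphabetError, make_alphabet


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class PatternExpr:
    """Node of a pattern syntax tree.

    kind is one of ``class`` (a set of alternative symbols — literals,
    bracket classes, negated classes and wildcards are all stored this
    way, with the distinction kept in ``source``), ``cat``, ``alt`` or
    ``rep`` with bounds ``lo <= hi < inf``.
    """

    kind: str
    children: tuple = ()
    symbols: frozenset = frozenset()  # for kind == "class": symbol indices
    lo: int = 0
    hi: int = 0
    source: str = ""

    # ---- constructors ----
    @staticmethod
    def symbol_class(indices, source: str = "") -> "PatternExpr":
        fs = frozenset(indices)
        if not fs:
            raise PatternError(f"empty symbol class {source!r}")
        return PatternExpr("class", symbols=fs, source=source)

    @staticmethod
    def cat(children, source: str = "") -> "PatternExpr":
        children = tuple(children)
        if not children:
            raise PatternError("empty concatenation")
        return PatternExpr("cat", children=children, source=source)

    @staticmethod
    def alt(children, source: str = "") -> "PatternExpr":
        children = tuple(children)
        if not children:
            raise PatternError("empty alternation")
        return PatternExpr("alt", children=children, source=source)

    @staticmethod
    def rep(child: "PatternExpr", lo: int, hi: int, source: str = "") -> "PatternExpr":
        if not (0 <= lo <= hi):
            raise PatternError(f"invalid repetition bounds ({lo},{hi})")
        return PatternExpr("rep", children=(child,), lo=lo, hi=hi, source=source)

    # ---- structural queries ----
    def min_len(self) -> int:
        if self.kind == "class":
            return 1
        if self.kind == "cat":
            return sum(c.min_len() for c in self.children)
        if self.kind == "alt":
            return min(c.min_len() for c in self.children)
        return self.lo * self.children[0].min_len()

    def max_len(self) -> int:
        if self.kind == "class":
            return 1
        if self.kind == "cat":
            return sum(c.max_len() for c in self.children)
        if self.kind == "alt":
            return max(c.max_len() for c in self.children)
        return self.hi * self.children[0].max_len()

    def fixed_len(self):
        """Common word length when all denoted words share one, else None."""
        lo, hi = self.min_len(), self.max_len()
        return lo if lo == hi else None

    def n_words_bound(self) -> int:
        """Upper bound on the number of denoted words (for expansion guards)."""
        if self.kind == "class":
            return len(self.symbols)
        if self.kind == "cat":
            return reduce(lambda a, b: a * b, (c.n_words_bound() for c in self.children), 1)
        if self.kind == "alt":
            return sum(c.n_words_bound() for c in self.children)
        n = self.children[0].n_words_bound()
        return sum(n**k for k in range(self.lo, self.hi + 1))

    def expand(self, guard: int = 100_000) -> set[tuple[int, ...]]:
        """Enumerate the denoted word set as tuples of symbol indices.

        Refuses when the bound on the number of words exceeds ``guard``.
        """
        if self.n_words_bound() > guard:
            raise PatternError(
                f"pattern expands to up to {self.n_words_bound()} words "
                f"(guard {guard}); use the automaton instead"
            )
        return self._expand()

    def _expand(self) -> set[tuple[int, ...]]:
        if self.kind == "class":
            return {(s,) for s in sorted(self.symbols)}
        if self.kind == "cat":
            out = {()}
            for c in self.children:
                out = {w + v for w in out for v in c._expand()}
            return out
        if self.kind == "alt":
            out: set = set()
            for c in self.children:
                out |= c._expand()
            return out
        base = self.children[0]._expand()
        out = set()
        level = {()}
        for k in range(self.hi + 1):
            if k >= self.lo:
                out |= level
            if k < self.hi:
                level = {w + v for w in level for v in base}
        return out


def _validate(expr: PatternExpr, alphabet: Alphabet) -> PatternExpr:
    if expr.min_len() < 1:
        raise PatternError("pattern denotes the empty word; words must be non-empty")
    n = len(alphabet)

    def walk(e):
        if e.kind == "class":
            if any(not (0 <= s < n) for s in e.symbols):
                raise PatternError(f"class {e.source!r} references symbols outside alphabet")
        for c in e.children:
            walk(c)

    walk(expr)
    return expr


# ---------------------------------------------------------------------------
# words dialect
# ---------------------------------------------------------------------------

def parse_words(words, alphabet) -> PatternExpr:
    """Parse an explicit list of words into an alternation of literals."""
    alphabet = make_alphabet(alphabet)
    words = list(words)
    if not words:
        raise PatternError("empty word list")
    branches = []
    for w in words:
        if not w:
            raise PatternError("empty word in word list")
        try:
            idx = alphabet.tokenize(w) if isinstance(w, str) else alphabet.encode(w)
        except AlphabetError as e:
            raise PatternError(f"in word {w!r}: {e}") from None
        branches.append(
            PatternExpr.cat(
                [PatternExpr.symbol_class({i}, source=alphabet.symbol(i)) for i in idx],
                source=str(w),
            )
        )
    if len(branches) == 1:
        expr = branches[0]
    else:
        expr = PatternExpr.alt(branches, source=" | ".join(map(str, words)))
    return _validate(expr, alphabet)


# ---------------------------------------------------------------------------
# PROSITE dialect
# ---------------------------------------------------------------------------

def parse_prosite(text: str, alphabet) -> PatternExpr:
    """Parse a PROSITE-syntax signature over the given (protein) alphabet."""
    alphabet = make_alphabet(alphabet)
    s = text.strip().rstrip(".")
    if "<" in s or ">" in s:
        raise PatternError(
            f"pattern {text!r}: anchors '<'/'>' are unsupported "
            "(occurrences are counted at every position)"
        )
    full = frozenset(range(len(alphabet)))
    elements: list[PatternExpr] = []
    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c == "-":
            i += 1
            continue
        if c in ("x", "X", "."):
            elem = PatternExpr.symbol_class(full, source="x")
            i += 1
        elif c == "[":
            j = s.find("]", i)
            if j < 0:
                raise PatternError(f"pattern {text!r}: unclosed '[' at position {i}")
            members = s[i + 1 : j]
            try:
                idx = {alphabet.index(ch) for ch in members}
            except AlphabetError:
                raise PatternError(
                    f"pattern {text!r}: unknown symbol in class at position {i}"
                ) from None
            elem = PatternExpr.symbol_class(idx, source=s[i : j + 1])
            i = j + 1
        elif c == "{":
            j = s.find("}", i)
            if j < 0:
                raise PatternError(f"pattern {text!r}: unclosed '{{' at position {i}")
            members = s[i + 1 : j]
            try:
                idx = full - {alphabet.index(ch) for ch in members}
            except AlphabetError:
                raise PatternError(
                    f"pattern {text!r}: unknown symbol in negated class at position {i}"
                ) from None
            elem = PatternExpr.symbol_class(idx, source=s[i : j + 1])
            i = j + 1
        elif c in alphabet:
            elem = PatternExpr.symbol_class({alphabet.index(c)}, source=c)
            i += 1
        else:
            raise PatternError(f"pattern {text!r}: unexpected character {c!r} at position {i}")
        # optional repetition suffix (n) or (n,m)
        if i < n and s[i] == "(":
            j = s.find(")", i)
            if j < 0:
                raise PatternError(f"pattern {text!r}: unclosed '(' at position {i}")
            body = s[i + 1 : j].replace(" ", "")
            parts = body.split(",")
            try:
                if len(parts) == 1:
                    lo = hi = int(parts[0])
                elif len(parts) == 2:
                    lo, hi = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternError(
                    f"pattern {text!r}: malformed repetition {s[i:j+1]!r} at position {i}"
                ) from None
            if not (0 <= lo <= hi):
                raise PatternError(
                    f"pattern {text!r}: invalid repetition bounds {s[i:j+1]!r}"
                )
            elem = PatternExpr.rep(elem, lo, hi, source=elem.source + s[i : j + 1])
            i = j + 1
        elements.append(elem)
    if not elements:
        raise PatternError(f"pattern {text!r} is empty")
    expr = elements[0] if len(elements) == 1 else PatternExpr.cat(elements, source=text)
    return _validate(expr, alphabet)


# ---------------------------------------------------------------------------
# IUPAC DNA dialect
# ---------------------------------------------------------------------------

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def parse_iupac_dna(word: str) -> PatternExpr:
    """Parse a DNA word with IUPAC degenerate codes over {A,C,G,T}."""
    alphabet = make_alphabet("dna")
    word = word.strip().upper()
    if not word:
        raise PatternError("empty IUPAC word")
    elems = []
    for pos, ch in enumerate(word):
        try:
            members = IUPAC_DNA[ch]
        except KeyError:
            raise PatternError(
                f"word {word!r}: unknown IUPAC code {ch!r} at position {pos}"
            ) from None
        elems.append(
            PatternExpr.symbol_class({alphabet.index(m) for m in members}, source=ch)
        )
    expr = elems[0] if len(elems) == 1 else PatternExpr.cat(elems, source=word)
    return _validate(expr, alphabet)


def parse_pattern(text, dialect: str, alphabet=None) -> PatternExpr:
    """Dispatch on dialect ∈ {'words', 'prosite', 'iupac-dna'}.

    For 'words', ``text`` may be a list of words or a whitespace-separated
    string.
    """
    if dialect == "words":
        words = text.split() if isinstance(text, str) else text
        return parse_words(words, alphabet)
    if dialect == "prosite":
        return parse_prosite(text, alphabet if alphabet is not None else "protein")
    if dialect == "iupac-dna":
        return parse_iupac_dna(text)
    raise PatternError(f"unknown pattern dialect {dialect!r}")
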