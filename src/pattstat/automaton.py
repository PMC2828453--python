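"""Compilation of patterns into minimal non-d-ambiguous DFAs.

The automaton recognizes the language A*·W of all texts ending with a
pattern occurrence.  Pipeline:

1. Glushkov position construction on the (finite-language) pattern
   expression — bounded repetitions are first rewritten into
   concatenations of optional copies, so the position automaton is
   epsilon-free;
2. sliding subset construction: DFA states are sets of pattern
   positions, with a fresh match attempt allowed at every text position
   (this realizes the A* prefix without an explicit nondeterministic
   self-loop state);
3. d-disambiguation by product with a register holding the last d
   symbols read, so that every state reachable by a text of length >= d
   determines its length-d history uniquely (the "d-th order DFA");
4. minimization by Moore partition refinement whose initial partition
   separates states by (finality, history) — ordinary minimization could
   merge states with different histories, which would leave the Markov
   transition probabilities attached to states ill-defined;
5. a verified merge pass folding states reachable only by texts shorter
   than d into language-equivalent history-carrying blocks when the
   quotient stays deterministic-consistent (for d = 1 this typically
   absorbs the start state, as in the classical automata for short
   protein signatures);
6. canonical relabeling breadth-first from the start state in alphabet
   order, so compiled automata are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Alphabet, make_alphabet
from .patterns import PatternExpr, PatternError


class DfaError(ValueError):
    pass


@dataclass(frozen=True)
class Dfa:
    """Complete deterministic automaton for A*·W with per-state history.

    ``history[q]`` is the unique length-d word (tuple of symbol indices)
    that every length->=d text reaching ``q`` ends with, or ``None`` for
    states reachable only by shorter texts.
    """

    alphabet: Alphabet
    order: int
    start: int
    trans: np.ndarray  # (L, |A|) int array
    finals: frozenset
    history: tuple  # tuple of tuple[int,...] | None, length L

    @property
    def n_states(self) -> int:
        return self.trans.shape[0]

    def is_final(self, q: int) -> bool:
        return q in self.finals

    def step(self, q: int, symbol: int) -> int:
        return int(self.trans[q, symbol])

    def walk(self, word) -> int:
        q = self.start
        for b in word:
            q = int(self.trans[q, b])
        return q

    def dump(self) -> str:
        """Tab-separated (state, symbol, next_state, is_final, history)."""
        lines = []
        for q in range(self.n_states):
            h = self.history[q]
            htxt = "".join(self.alphabet.symbol(b) for b in h) if h is not None else "-"
            for b in range(len(self.alphabet)):
                lines.append(
                    f"{q}\t{self.alphabet.symbol(b)}\t{int(self.trans[q, b])}"
                    f"\t{int(q in self.finals)}\t{htxt}"
                )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Glushkov position construction
# ---------------------------------------------------------------------------

def _rewrite_reps(e: PatternExpr) -> PatternExpr:
    """Expand bounded repetitions into concatenations of optional copies."""
    if e.kind == "class":
        return e
    if e.kind in ("cat", "alt"):
        kids = tuple(_rewrite_reps(c) for c in e.children)
        return PatternExpr(e.kind, children=kids, source=e.source)
    child = _rewrite_reps(e.children[0])
    parts = [child] * e.lo
    # optional copy: alternation with an epsilon marker node
    eps = PatternExpr("eps")
    for _ in range(e.hi - e.lo):
        parts.append(PatternExpr("alt", children=(child, eps), source=e.source + "?"))
    if not parts:
        return eps
    if len(parts) == 1:
        return parts[0]
    return PatternExpr("cat", children=tuple(parts), source=e.source)


def _glushkov(expr: PatternExpr):
    """Return (classes, first, last, follow) for an epsilon-free match.

    ``classes[p]`` is the symbol set of position p; positions are
    assigned in left-to-right traversal order, so shared sub-expression
    objects occurring several times get distinct positions.
    """
    classes: list[frozenset] = []
    follow: list[set] = []

    def visit(e):
        # returns (nullable, first, last) with follow updated in place
        if e.kind == "eps":
            return True, frozenset(), frozenset()
        if e.kind == "class":
            p = len(classes)
            classes.append(e.symbols)
            follow.append(set())
            return False, frozenset([p]), frozenset([p])
        if e.kind == "alt":
            nul, fst, lst = False, frozenset(), frozenset()
            for c in e.children:
                n, f, l = visit(c)
                nul |= n
                fst |= f
                lst |= l
            return nul, fst, lst
        if e.kind == "cat":
            nul, fst, lst = True, frozenset(), frozenset()
            for c in e.children:
                n, f, l = visit(c)
                for p in lst:
                    follow[p] |= f
                if nul:
                    fst |= f
                if n:
                    lst |= l
                else:
                    lst = l
                nul &= n
            return nul, fst, lst
        raise PatternError(f"unexpected node kind {e.kind!r} after rewrite")

    nul, fst, lst = visit(_rewrite_reps(expr))
    if nul:
        raise PatternError("pattern denotes the empty word")
    return classes, fst, lst, follow


# ---------------------------------------------------------------------------
# subset construction for A*·W
# ---------------------------------------------------------------------------

def _subset_automaton(expr: PatternExpr, n_symbols: int):
    classes, first, last, follow = _glushkov(expr)
    # positions matching each symbol, as python sets for fast intersection
    by_symbol = [frozenset(p for p, cl in enumerate(classes) if b in cl)
                 for b in range(n_symbols)]
    first_by_symbol = [first & by_symbol[b] for b in range(n_symbols)]

    start = frozenset()
    index = {start: 0}
    states = [start]
    trans_rows = []
    finals = set()
    i = 0
    while i < len(states):
        S = states[i]
        if S & last:
            finals.add(i)
        reach = set()
        for q in S:
            reach |= follow[q]
        row = []
        for b in range(n_symbols):
            T = frozenset((reach & by_symbol[b]) | first_by_symbol[b])
            j = index.get(T)
            if j is None:
                j = len(states)
                index[T] = j
                states.append(T)
            row.append(j)
        trans_rows.append(row)
        i += 1
    trans = np.array(trans_rows, dtype=np.int64)
    return trans, finals, 0


# ---------------------------------------------------------------------------
# d-disambiguation
# ---------------------------------------------------------------------------

def _disambiguate(trans, finals, start, d: int):
    """Product with a last-d-symbols register; BFS over reachable pairs."""
    n_symbols = trans.shape[1]
    start_pair = (start, ())
    index = {start_pair: 0}
    pairs = [start_pair]
    rows = []
    i = 0
    while i < len(pairs):
        q, w = pairs[i]
        row = []
        for b in range(n_symbols):
            w2 = (w + (b,))[-d:] if d > 0 else ()
            pair = (int(trans[q, b]), w2)
            j = index.get(pair)
            if j is None:
                j = len(pairs)
                index[pair] = j
                pairs.append(pair)
            row.append(j)
        rows.append(row)
        i += 1
    new_trans = np.array(rows, dtype=np.int64)
    new_finals = frozenset(i for i, (q, _) in enumerate(pairs) if q in finals)
    history = tuple(w if len(w) == d else None for _, w in pairs)
    short = tuple(w for _, w in pairs)  # actual short prefix for undefined states
    return new_trans, new_finals, 0, history, short


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def _moore_refine(trans, block):
    """Refine a partition to the coarsest stable one (numpy Moore rounds)."""
    n_blocks = block.max() + 1
    while True:
        rows = np.column_stack([block, block[trans]])
        _, new_block = np.unique(rows, axis=0, return_inverse=True)
        new_n = new_block.max() + 1
        if new_n == n_blocks:
            return new_block
        block, n_blocks = new_block, new_n


def _minimize(trans, finals, start, history, short):
    n = trans.shape[0]
    finals_arr = np.zeros(n, dtype=np.int64)
    for q in finals:
        finals_arr[q] = 1
    # initial blocks keyed by (finality, history) with short-history states
    # kept apart (their key includes the unique short prefix reaching them)
    keys = {}
    block = np.empty(n, dtype=np.int64)
    for q in range(n):
        k = (int(finals_arr[q]), history[q] if history[q] is not None else ("short", short[q]))
        block[q] = keys.setdefault(k, len(keys))
    block = _moore_refine(trans, block)

    # try to fold each short-history block into a compatible defined block
    short_states = [q for q in range(n) if history[q] is None]
    for s in short_states:
        sig_s = (int(finals_arr[s]), tuple(int(block[t]) for t in trans[s]))
        for q in range(n):
            if block[q] == block[s] or history[q] is None:
                continue
            sig_q = (int(finals_arr[q]), tuple(int(block[t]) for t in trans[q]))
            if sig_q != sig_s:
                continue
            trial = block.copy()
            trial[trial == block[s]] = block[q]
            trial = _moore_refine(trans, np.unique(trial, return_inverse=True)[1])
            if trial[s] == trial[q]:
                block = trial
                break

    # quotient automaton
    n_blocks = int(block.max() + 1)
    rep = np.zeros(n_blocks, dtype=np.int64)
    # prefer a defined-history representative for merged blocks
    seen = set()
    for q in range(n):
        b = int(block[q])
        if b not in seen or (history[rep[b]] is None and history[q] is not None):
            rep[b] = q
            seen.add(b)
    q_trans = block[trans[rep]]
    q_finals = frozenset(int(block[q]) for q in finals)
    q_history = tuple(history[rep[b]] for b in range(n_blocks))
    return q_trans, q_finals, int(block[start]), q_history


def _canonical(trans, finals, start, history):
    """BFS relabeling from the start state in alphabet order."""
    n = trans.shape[0]
    order = np.full(n, -1, dtype=np.int64)
    order[start] = 0
    queue = [start]
    nxt = 1
    while queue:
        q = queue.pop(0)
        for t in trans[q]:
            t = int(t)
            if order[t] < 0:
                order[t] = nxt
                nxt += 1
                queue.append(t)
    if nxt != n:  # unreachable states (should not happen) are dropped
        keep = np.flatnonzero(order >= 0)
        inv = {int(q): int(order[q]) for q in keep}
        new_trans = np.empty((nxt, trans.shape[1]), dtype=np.int64)
        for q in keep:
            new_trans[inv[int(q)]] = [inv[int(t)] for t in trans[q]]
        new_finals = frozenset(inv[q] for q in finals if q in inv)
        new_history = [None] * nxt
        for q in keep:
            new_history[inv[int(q)]] = history[int(q)]
        return new_trans, new_finals, 0, tuple(new_history)
    perm = order
    new_trans = np.empty_like(trans)
    new_history = [None] * n
    for q in range(n):
        new_trans[perm[q]] = perm[trans[q]]
        new_history[perm[q]] = history[q]
    new_finals = frozenset(int(perm[q]) for q in finals)
    return new_trans, new_finals, 0, tuple(new_history)


def compile_dfa(expr: PatternExpr, alphabet, order: int = 1) -> Dfa:
    """Compile a pattern into the minimal non-d-ambiguous DFA for A*·W."""
    alphabet = make_alphabet(alphabet)
    if order < 0:
        raise DfaError("Markov order must be >= 0")
    if expr.min_len() < 1:
        raise DfaError("pattern denotes empty words")
    if expr.min_len() < order:
        raise DfaError(
            f"pattern contains words of length {expr.min_len()} < order d={order}; "
            "occurrences inside the initial context are not supported"
        )
    trans, finals, start = _subset_automaton(expr, len(alphabet))
    trans, finals, start, history, short = _disambiguate(trans, finals, start, order)
    trans, finals, start, history = _minimize(trans, finals, start, history, short)
    trans, finals, start, history = _canonical(trans, finals, start, history)
    return Dfa(
        alphabet=alphabet,
        order=order,
        start=start,
        trans=trans,
        finals=finals,
        history=history,
    )


def scan(dfa: Dfa, sequence) -> tuple[int, list[int]]:
    """Count pattern occurrences in a sequence; returns (count, 1-based ends).

    ``sequence`` is a list of symbol indices or of symbol tokens.
    Overlapping occurrences are all counted: position i is an end
    position iff the automaton is in a final state after reading the
    first i symbols.
    """
    seq = [
        b if isinstance(b, (int, np.integer)) else dfa.alphabet.index(b)
        for b in sequence
    ]
    q = dfa.start
    ends = []
    for i, b in enumerate(seq, start=1):
        if not (0 <= b < len(dfa.alphabet)):
            raise DfaError(f"symbol index {b} out of range at position {i}")
        q = int(dfa.trans[q, b])
        if q in dfa.finals:
            ends.append(i)
    return len(ends), ends
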