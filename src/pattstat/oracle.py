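"""Independent brute-force oracles and reproducible random fixtures.

Everything here deliberately avoids the automaton/embedding machinery:
occurrence counting is done by direct suffix testing against the
expanded word set, and count distributions by exhaustive enumeration of
all sequence tuples weighted by their exact Markov probability.  These
are the reference implementations that the fast algorithms are tested
against on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alphabet import Alphabet, make_alphabet
from .markov import HeterogeneousModel, HomogeneousModel, context_words
from .patterns import PatternError, PatternExpr, parse_words

EXPANSION_GUARD = 100_000
ENUMERATION_BUDGET = 10_000_000


class OracleError(ValueError):
    pass


def naive_count(expr: PatternExpr, sequence, guard: int = EXPANSION_GUARD):
    """Count matching positions by testing every suffix of every prefix.

    Returns (count, 1-based end positions).  Overlapping occurrences
    all count.  No automaton involved: the pattern is expanded to its
    word set (refused above ``guard`` words).
    """
    try:
        words = expr.expand(guard)
    except PatternError as e:
        raise OracleError(str(e)) from None
    seq = tuple(sequence)
    lens = sorted({len(w) for w in words})
    ends = []
    for i in range(1, len(seq) + 1):
        for k in lens:
            if k <= i and seq[i - k : i] in words:
                ends.append(i)
                break
    return len(ends), ends


def _sequence_probability(model, seq) -> float:
    d = model.order
    n = len(model.alphabet)
    ctx_index = {w: i for i, w in enumerate(context_words(n, d))}
    mu = model.start_word_distribution()
    p = float(mu[ctx_index[tuple(seq[:d])]]) if d > 0 else 1.0
    for t in range(len(seq) - d):
        table = (
            model.table_at(t + 1)
            if isinstance(model, HeterogeneousModel)
            else model.trans
        )
        p *= float(table[ctx_index[tuple(seq[t : t + d])] if d > 0 else 0, seq[t + d]])
    return p


def _single_sequence_distribution(model, expr, length, start=None) -> dict[int, float]:
    """Exact count distribution in one sequence by full enumeration.

    ``start`` optionally overrides the model's starting distribution
    (a length-d word or a distribution over context words).
    """
    n = len(model.alphabet)
    d = model.order
    ctx = context_words(n, d)
    if d == 0:
        mu = np.ones(1)
    elif start is None:
        mu = model.start_word_distribution()
    elif isinstance(start, (str, list, tuple)):
        word = (
            model.alphabet.tokenize(start) if isinstance(start, str) else
            [model.alphabet.index(b) if isinstance(b, str) else int(b) for b in start]
        )
        mu = np.zeros(len(ctx))
        mu[ctx.index(tuple(word))] = 1.0
    else:
        mu = np.asarray(start, dtype=float)
    words = expr.expand(EXPANSION_GUARD)
    lens = sorted({len(w) for w in words})
    out: dict[int, float] = {}
    for ci, w in enumerate(ctx):
        if d > 0 and mu[ci] == 0:
            continue
        base_p = float(mu[ci]) if d > 0 else 1.0
        for tail in itertools.product(range(n), repeat=length - d):
            seq = w + tail
            p = base_p
            for t in range(length - d):
                table = (
                    model.table_at(t + 1)
                    if isinstance(model, HeterogeneousModel)
                    else model.trans
                )
                row = table[0] if d == 0 else table[
                    _ctx_idx_cache(model)[seq[t : t + d]]
                ]
                p *= float(row[seq[t + d]])
            k = 0
            for i in range(1, length + 1):
                for wl in lens:
                    if wl <= i and seq[i - wl : i] in words:
                        k += 1
                        break
            out[k] = out.get(k, 0.0) + p
        if d == 0:
            break
    return out


_CTX_CACHE: dict = {}


def _ctx_idx_cache(model):
    key = (len(model.alphabet), model.order)
    if key not in _CTX_CACHE:
        _CTX_CACHE[key] = {
            w: i for i, w in enumerate(context_words(*key))
        }
    return _CTX_CACHE[key]


def brute_force_distribution(models, expr, lengths, starts=None) -> dict[int, float]:
    """Exact distribution of N = sum N_j by exhaustive enumeration.

    ``models`` is one model per sequence (or a single model applied to
    all).  Each sequence tuple is weighted by its exact Markov
    probability; heterogeneous models are supported.  Refused when
    |A|^sum(l_j) exceeds the enumeration budget.
    """
    if isinstance(models, (HomogeneousModel, HeterogeneousModel)):
        models = [models] * len(lengths)
    n = len(models[0].alphabet)
    cost = sum(n**ell for ell in lengths)
    if cost > ENUMERATION_BUDGET:
        raise OracleError(
            f"enumeration requires ~{cost} sequence evaluations "
            f"(budget {ENUMERATION_BUDGET})"
        )
    per_seq = []
    for j, (model, ell) in enumerate(zip(models, lengths)):
        start = None if starts is None else starts[j]
        per_seq.append(_single_sequence_distribution(model, expr, ell, start))
    # convolve the per-sequence distributions (independence)
    out = {0: 1.0}
    for dist in per_seq:
        nxt: dict[int, float] = {}
        for a, pa in out.items():
            for b, pb in dist.items():
                nxt[a + b] = nxt.get(a + b, 0.0) + pa * pb
        out = nxt
    return out


# ---------------------------------------------------------------------------
# random fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """Seeded random model + pattern + length plan, fully reproducible."""

    seed: int
    alphabet: Alphabet
    model: object
    expr: PatternExpr
    words: tuple
    lengths: tuple
    starts: tuple


def dump_fixture(fixture: "Fixture", directory, seed: int | None = None) -> dict:
    """Write a fixture as model JSON + pattern text + simulated FASTA.

    Makes random instances usable as end-to-end command-line inputs.
    Returns the written paths.
    """
    from pathlib import Path

    from .markov import model_to_json, simulate

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": directory / "model.json",
        "patterns": directory / "patterns.txt",
        "fasta": directory / "sequences.fa",
        "alphabet": directory / "alphabet.txt",
    }
    paths["model"].write_text(model_to_json(fixture.model))
    paths["patterns"].write_text(" ".join(fixture.words) + "\n")
    paths["alphabet"].write_text("\n".join(fixture.alphabet.symbols) + "\n")
    seqs = simulate(
        fixture.model,
        list(fixture.lengths),
        starts=list(fixture.starts),
        seed=fixture.seed if seed is None else seed,
    )
    with open(paths["fasta"], "w") as fh:
        for j, s in enumerate(seqs):
            fh.write(f">seq_{j}\n{''.join(fixture.alphabet.decode(s))}\n")
    return paths


def make_fixture(
    seed: int,
    n_symbols: int = 2,
    order: int = 1,
    n_words: int = 2,
    word_len: tuple = (2, 4),
    lengths: tuple = (5, 6),
    heterogeneous: bool = False,
) -> Fixture:
    """Draw a random instance: Dirichlet(1,..,1) transition rows (full
    support, hence irreducible and aperiodic), a random word set, and
    fixed-word starts."""
    rng = np.random.default_rng(seed)
    symbols = tuple("abcdefgh"[:n_symbols])
    alphabet = make_alphabet(symbols)
    m = n_symbols**order
    words = set()
    while len(words) < n_words:
        k = int(rng.integers(max(word_len[0], order, 1), word_len[1] + 1))
        words.add("".join(rng.choice(list(symbols), size=k)))
    words = tuple(sorted(words))
    expr = parse_words(list(words), alphabet)
    start = np.asarray(rng.dirichlet(np.ones(m)))
    if heterogeneous:
        n_trans = max(lengths) - order
        trans = np.asarray(rng.dirichlet(np.ones(n_symbols), size=(n_trans, m)))
        model = HeterogeneousModel(
            alphabet=alphabet, order=order, trans=trans, start=start
        )
    else:
        trans = np.asarray(rng.dirichlet(np.ones(n_symbols), size=m))
        model = HomogeneousModel(
            alphabet=alphabet, order=order, trans=trans, start=start
        )
    ctx = context_words(n_symbols, order)
    starts = tuple(
        "".join(alphabet.symbol(b) for b in ctx[int(rng.integers(m))])
        for _ in lengths
    )
    return Fixture(
        seed=seed,
        alphabet=alphabet,
        model=model,
        expr=expr,
        words=words,
        lengths=tuple(lengths),
        starts=starts,
    )
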