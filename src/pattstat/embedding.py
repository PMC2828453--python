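"""Markov chain embedding of a pattern problem over DFA states.

A non-d-ambiguous DFA makes the state process Y_i = delta(sigma,
X_1..X_i) a (possibly heterogeneous) order-1 Markov chain over the L
automaton states: each state carries its length-d history, so the
order-d transition probabilities of the source apply unambiguously.
The transition matrix splits as T = P + Q, where Q holds the *counting
transitions* — those entering a final state, i.e. completing a pattern
occurrence.  Tagging Q with a dummy variable y turns state propagation
into a moment generating function computation.

States of the minimized DFA that are reachable only by texts shorter
than d have no history and zero start mass; they are dropped from the
embedding (the re-indexing is recorded in ``state_map``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .automaton import Dfa
from .markov import HeterogeneousModel, HomogeneousModel


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddedChain:
    """The L-state embedded chain with sparse transition split T = P + Q.

    For homogeneous models ``P``/``Q`` are fixed CSR matrices; for
    heterogeneous models :meth:`matrices_at` builds the pair for each
    1-based transition index i (governing the symbol at position i + d).
    Each row of P + Q sums to 1; Q's non-zero columns are exactly the
    final states.
    """

    dfa: Dfa
    model: object
    state_map: np.ndarray  # DFA state -> embedded index, -1 if dropped
    final_mask: np.ndarray  # bool over embedded states
    P: sp.csr_matrix | None = None
    Q: sp.csr_matrix | None = None
    _rows: np.ndarray = field(default=None, repr=False)
    _cols: np.ndarray = field(default=None, repr=False)
    _ctx: np.ndarray = field(default=None, repr=False)
    _sym: np.ndarray = field(default=None, repr=False)

    @property
    def L(self) -> int:
        return int(self.final_mask.shape[0])

    @property
    def homogeneous(self) -> bool:
        return isinstance(self.model, HomogeneousModel)

    def matrices_at(self, i: int) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """(P_i, Q_i) for the transition emitting position i + d (i >= 1)."""
        if self.homogeneous:
            return self.P, self.Q
        table = self.model.table_at(i)  # raises on out-of-range
        return self._weigh(table)

    def _weigh(self, table: np.ndarray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        data = table[self._ctx, self._sym]
        tgt_final = self.final_mask[self._cols]
        L = self.L
        P = sp.csr_matrix(
            (data[~tgt_final], (self._rows[~tgt_final], self._cols[~tgt_final])),
            shape=(L, L),
        )
        Q = sp.csr_matrix(
            (data[tgt_final], (self._rows[tgt_final], self._cols[tgt_final])),
            shape=(L, L),
        )
        return P, Q


def _build(dfa: Dfa, model) -> EmbeddedChain:
    if dfa.order != model.order:
        raise EmbeddingError(
            f"DFA order {dfa.order} != model order {model.order}; recompile the DFA"
        )
    n = len(dfa.alphabet)
    kept = [q for q in range(dfa.n_states) if dfa.history[q] is not None]
    state_map = np.full(dfa.n_states, -1, dtype=np.int64)
    for i, q in enumerate(kept):
        state_map[q] = i
    final_mask = np.zeros(len(kept), dtype=bool)
    for q in dfa.finals:
        if state_map[q] >= 0:
            final_mask[state_map[q]] = True
    from .markov import context_words

    ctx_index = {w: i for i, w in enumerate(context_words(n, model.order))}
    rows, cols, ctxs, syms = [], [], [], []
    for q in kept:
        try:
            ctx = ctx_index[dfa.history[q]] if model.order > 0 else 0
        except KeyError:
            raise EmbeddingError(
                f"context {dfa.history[q]} of state {q} absent from the model"
            ) from None
        for b in range(n):
            t = int(dfa.trans[q, b])
            # targets of kept states are reachable by length >= d+1 texts
            rows.append(int(state_map[q]))
            cols.append(int(state_map[t]))
            ctxs.append(ctx)
            syms.append(b)
    chain = EmbeddedChain(
        dfa=dfa,
        model=model,
        state_map=state_map,
        final_mask=final_mask,
        _rows=np.array(rows),
        _cols=np.array(cols),
        _ctx=np.array(ctxs),
        _sym=np.array(syms),
    )
    return chain


def embed(dfa: Dfa, model: HomogeneousModel) -> EmbeddedChain:
    """Embed a homogeneous model: fixed P and Q of size L x L."""
    if not isinstance(model, HomogeneousModel):
        raise EmbeddingError("embed() needs a homogeneous model; see embed_heterogeneous")
    chain = _build(dfa, model)
    chain.P, chain.Q = chain._weigh(model.trans)
    return chain


def embed_heterogeneous(dfa: Dfa, model: HeterogeneousModel) -> EmbeddedChain:
    """Embed a heterogeneous model: position-indexed (P_i, Q_i) factory."""
    if not isinstance(model, HeterogeneousModel):
        raise EmbeddingError("embed_heterogeneous() needs a heterogeneous model")
    return _build(dfa, model)


def dump_coo(chain: EmbeddedChain, position: int | None = None) -> str:
    """Coordinate-format dump of the transition split, for inspection.

    Tab-separated (row, col, value, is_counting) lines; ``position``
    selects the table of a heterogeneous chain (1-based, default 1).
    """
    if chain.homogeneous:
        P, Q = chain.P, chain.Q
    else:
        P, Q = chain.matrices_at(1 if position is None else position)
    lines = []
    for mat, counting in ((P, 0), (Q, 1)):
        coo = mat.tocoo()
        for r, c, v in zip(coo.row, coo.col, coo.data):
            lines.append(f"{r}\t{c}\t{float(v)!r}\t{counting}")
    lines.sort(key=lambda s: (int(s.split("\t")[0]), int(s.split("\t")[1])))
    return "\n".join(lines) + "\n"


def start_vector(chain: EmbeddedChain, start) -> tuple[np.ndarray, int]:
    """Map a distribution over length-d words to states: m_d.

    ``start`` is a distribution over the model's context words (or a
    length-d word / single symbol for a point mass).  Returns
    ``(m, initial_occurrences)`` where ``m`` is the start distribution
    over embedded states and ``initial_occurrences`` is 1 when the mass
    sits on final states (a pattern word of length exactly d occurs at
    position d — that mass contributes a factor y downstream) else 0.
    Mixed support (part final, part not) is resolved per-state by the
    moment generating function routines, which read ``final_mask``.
    """
    model = chain.model
    dfa = chain.dfa
    if isinstance(start, (str, list, tuple)):
        word = start
        if isinstance(word, str):
            word = dfa.alphabet.tokenize(word)
        dist = np.zeros(len(dfa.alphabet) ** dfa.order)
        from .markov import context_words

        idx = {w: i for i, w in enumerate(context_words(len(dfa.alphabet), dfa.order))}
        dist[idx[tuple(word)]] = 1.0
    else:
        dist = np.asarray(start, dtype=float)
    if abs(dist.sum() - 1.0) > 1e-9:
        raise EmbeddingError("start distribution does not sum to 1")
    from .markov import context_words

    m = np.zeros(chain.L)
    any_final = 0
    for i, w in enumerate(context_words(len(dfa.alphabet), dfa.order)):
        if dist[i] == 0:
            continue
        q = dfa.walk(w)
        e = int(chain.state_map[q])
        if e < 0:
            raise EmbeddingError(f"state for start word {w} dropped from embedding")
        m[e] += dist[i]
        if chain.final_mask[e]:
            any_final = 1
    return m, any_final
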