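"""Homogeneous and heterogeneous order-d Markov sources over an alphabet.

Models are parameterized by a starting distribution mu_1 over length-d
context words and transition probabilities pi(w, b) from a context w to
the next symbol b.  Heterogeneous models carry one transition table per
position, as produced e.g. by the sliding-window estimator.

Contexts are enumerated in lexicographic order of their symbol indices;
for order d the context space has |A|^d elements (a single empty context
for d = 0).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alphabet import Alphabet, make_alphabet

ROW_TOL = 1e-12


class ModelError(ValueError):
    pass


def context_words(n_symbols: int, d: int) -> list[tuple[int, ...]]:
    return [tuple(w) for w in itertools.product(range(n_symbols), repeat=d)]


def _check_rows(mat: np.ndarray, what: str) -> None:
    if np.any(mat < -ROW_TOL) or np.any(mat > 1 + ROW_TOL):
        raise ModelError(f"{what}: probabilities outside [0, 1]")
    bad = np.flatnonzero(np.abs(mat.sum(axis=1) - 1.0) > 1e-9)
    if bad.size:
        raise ModelError(f"{what}: rows {bad.tolist()} do not sum to 1")


@dataclass(frozen=True)
class HomogeneousModel:
    """Order-d homogeneous Markov chain.

    ``trans`` has shape (|A|^d, |A|): row w gives pi(w, .).  ``start``
    is the distribution mu_1 over length-d context words (uniform in a
    single point for a fixed starting word), or None when unspecified.
    """

    alphabet: Alphabet
    order: int
    trans: np.ndarray
    start: np.ndarray | None = None
    _ctx_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.alphabet)
        expected = (n**self.order, n)
        if self.trans.shape != expected:
            raise ModelError(f"transition table shape {self.trans.shape} != {expected}")
        _check_rows(self.trans, "transition table")
        if self.start is not None:
            if self.start.shape != (n**self.order,):
                raise ModelError("start distribution has wrong length")
            if abs(self.start.sum() - 1.0) > 1e-9:
                raise ModelError("start distribution does not sum to 1")
        ctx = context_words(n, self.order)
        object.__setattr__(self, "_ctx_index", {w: i for i, w in enumerate(ctx)})

    @property
    def contexts(self) -> list[tuple[int, ...]]:
        return context_words(len(self.alphabet), self.order)

    def context_index(self, word) -> int:
        key = tuple(
            b if isinstance(b, (int, np.integer)) else self.alphabet.index(b)
            for b in word
        )
        return self._ctx_index[key]

    def prob(self, context, symbol: int) -> float:
        return float(self.trans[self.context_index(context), symbol])

    def context_matrix(self) -> np.ndarray:
        """Transition matrix on the |A|^d context space (the order-1 lift).

        Context w = (w1..wd) moves to (w2..wd, b) with probability
        pi(w, b); for d <= 1 this is the transition table itself.
        """
        n = len(self.alphabet)
        if self.order == 0:
            return np.ones((1, 1))
        if self.order == 1:
            return self.trans.copy()
        m = n**self.order
        out = np.zeros((m, m))
        for i, w in enumerate(self.contexts):
            for b in range(n):
                j = self._ctx_index[w[1:] + (b,)]
                out[i, j] += self.trans[i, b]
        return out

    def start_word_distribution(self) -> np.ndarray:
        if self.start is None:
            raise ModelError("model has no starting distribution")
        return self.start

    def fixed_start(self, word) -> np.ndarray:
        """Point-mass starting distribution on a given length-d word."""
        word = tuple(
            self.alphabet.index(b) if isinstance(b, str) else int(b) for b in word
        )
        if len(word) != self.order:
            raise ModelError(
                f"start word length {len(word)} != model order {self.order}"
            )
        v = np.zeros(len(self.alphabet) ** self.order)
        v[self._ctx_index[word]] = 1.0
        return v


@dataclass(frozen=True)
class HeterogeneousModel:
    """Position-indexed order-d Markov chain supporting lengths <= ell.

    ``trans[i]`` (0-based, i = 0..ell-d-1) governs the transition that
    emits symbol X_{i+d+1}, i.e. the paper-style pi_{i+1}.
    """

    alphabet: Alphabet
    order: int
    trans: np.ndarray  # (ell - d, |A|^d, |A|)
    start: np.ndarray

    def __post_init__(self):
        n = len(self.alphabet)
        if self.trans.ndim != 3 or self.trans.shape[1:] != (n**self.order, n):
            raise ModelError("heterogeneous transition array has wrong shape")
        for i in range(self.trans.shape[0]):
            _check_rows(self.trans[i], f"pi_{i+1}")
        if abs(self.start.sum() - 1.0) > 1e-9:
            raise ModelError("start distribution does not sum to 1")

    @property
    def length(self) -> int:
        return self.trans.shape[0] + self.order

    def table_at(self, i: int) -> np.ndarray:
        """Transition table pi_i (1-based transition index)."""
        if not (1 <= i <= self.trans.shape[0]):
            raise ModelError(
                f"position index {i} outside supported range 1..{self.trans.shape[0]}"
            )
        return self.trans[i - 1]

    def start_word_distribution(self) -> np.ndarray:
        return self.start


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_index_sequences(sequences, alphabet: Alphabet) -> list[list[int]]:
    out = []
    for s in sequences:
        if isinstance(s, str):
            out.append(alphabet.tokenize(s))
        else:
            out.append(
                [b if isinstance(b, (int, np.integer)) else alphabet.index(b) for b in s]
            )
    return out


def _start_distribution(seqs: list[list[int]], n: int, d: int) -> np.ndarray:
    mu = np.zeros(n**d)
    if d == 0:
        mu[0] = 1.0
        return mu
    ctx_index = {w: i for i, w in enumerate(context_words(n, d))}
    for s in seqs:
        mu[ctx_index[tuple(s[:d])]] += 1.0
    return mu / mu.sum()


def fit_homogeneous(sequences, alphabet, order: int = 1, pseudocount: float = 0.0):
    """Maximum-likelihood fit of a homogeneous order-d model.

    pi(w, b) = (#(w·b) + pseudocount) / (#(w·*) + |A|·pseudocount),
    counts pooled over all sequences.  The starting distribution is the
    empirical distribution of each sequence's first d symbols.  With
    pseudocount 0, contexts never followed by a symbol are a hard error:
    silently filling them would change downstream P-values invisibly.
    """
    alphabet = make_alphabet(alphabet)
    n = len(alphabet)
    seqs = _as_index_sequences(sequences, alphabet)
    if any(len(s) < order + 1 for s in seqs):
        raise ModelError(f"every sequence must have length >= d+1 = {order + 1}")
    counts = np.zeros((n**order, n))
    ctx_index = {w: i for i, w in enumerate(context_words(n, order))}
    for s in seqs:
        for t in range(len(s) - order):
            counts[ctx_index[tuple(s[t : t + order])], s[t + order]] += 1.0
    counts += pseudocount
    denom = counts.sum(axis=1)
    if np.any(denom == 0):
        missing = [
            "".join(alphabet.symbol(b) for b in context_words(n, order)[i])
            for i in np.flatnonzero(denom == 0)
        ]
        raise ModelError(
            f"contexts never observed (and pseudocount = 0): {missing}; "
            "supply a pseudocount or a fuller data set"
        )
    trans = counts / denom[:, None]
    start = _start_distribution(seqs, n, order)
    return HomogeneousModel(alphabet=alphabet, order=order, trans=trans, start=start)


def fit_heterogeneous_window(sequences, alphabet, order: int = 1, window: int = 200):
    """Sliding-window MLE of a heterogeneous model on equal-length sequences.

    The table governing the transition at position t (emitting symbol
    t + d) pools counts over transitions whose context starts inside the
    window [t - w//2, t + w//2] clipped to the sequence, across all
    sequences.  With window >= sequence length this reduces exactly to
    the homogeneous fit at every position.
    """
    alphabet = make_alphabet(alphabet)
    n = len(alphabet)
    seqs = _as_index_sequences(sequences, alphabet)
    if not seqs:
        raise ModelError("no sequences")
    ell = len(seqs[0])
    if any(len(s) != ell for s in seqs):
        raise ModelError("heterogeneous fit requires equal-length sequences")
    if window < order + 1:
        raise ModelError(f"window {window} < d+1 = {order + 1}")
    ctx_index = {w: i for i, w in enumerate(context_words(n, order))}
    # per-position transition counts, then windowed cumulative sums
    n_trans = ell - order
    pos_counts = np.zeros((n_trans, n**order, n))
    for s in seqs:
        for t in range(n_trans):
            pos_counts[t, ctx_index[tuple(s[t : t + order])], s[t + order]] += 1.0
    csum = np.concatenate(
        [np.zeros((1, n**order, n)), np.cumsum(pos_counts, axis=0)], axis=0
    )
    half = window // 2
    trans = np.empty_like(pos_counts)
    for t in range(n_trans):
        lo = max(0, t - half)
        hi = min(n_trans, t + half + 1)
        counts = csum[hi] - csum[lo]
        denom = counts.sum(axis=1)
        if np.any(denom == 0):
            i = int(np.flatnonzero(denom == 0)[0])
            ctx = "".join(alphabet.symbol(b) for b in context_words(n, order)[i])
            raise ModelError(
                f"no counts for context {ctx!r} in window around position {t + 1}"
            )
        trans[t] = counts / denom[:, None]
    start = _start_distribution(seqs, n, order)
    return HeterogeneousModel(alphabet=alphabet, order=order, trans=trans, start=start)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralDiagnostics:
    second_eigenvalue_magnitude: float
    stationary: np.ndarray  # over contexts
    convergence_horizon: int


def _check_ergodic(mat: np.ndarray) -> None:
    g = nx.DiGraph()
    m = mat.shape[0]
    g.add_nodes_from(range(m))
    for i, j in zip(*np.nonzero(mat > 0)):
        g.add_edge(int(i), int(j))
    comps = list(nx.strongly_connected_components(g))
    if len(comps) > 1:
        raise ModelError(
            f"context chain is reducible: {len(comps)} communicating classes "
            f"{[sorted(c) for c in comps]}"
        )
    if not nx.is_aperiodic(g):
        raise ModelError("context chain is periodic")


def stationary_distribution(model: HomogeneousModel) -> np.ndarray:
    """Left fixed vector of the context transition matrix.

    Requires irreducibility and aperiodicity; the residual
    ||vP - v||_inf is verified below 1e-10.
    """
    mat = model.context_matrix()
    if model.order == 0:
        return np.ones(1)
    _check_ergodic(mat)
    vals, vecs = np.linalg.eig(mat.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    v /= v.sum()
    if np.max(np.abs(v @ mat - v)) > 1e-10:
        raise ModelError("stationary distribution residual above 1e-10")
    return v


def stationary_symbol_distribution(model: HomogeneousModel) -> np.ndarray:
    """Stationary marginal over symbols (contexts marginalized)."""
    if model.order == 0:
        return model.trans[0].copy()
    v = stationary_distribution(model)
    n = len(model.alphabet)
    out = np.zeros(n)
    for i, w in enumerate(model.contexts):
        out[w[-1]] += v[i]
    return out


def spectral_diagnostics(model: HomogeneousModel, tolerance: float = 1e-15):
    """Second-eigenvalue magnitude mu and the convergence horizon.

    The horizon is the smallest number of steps after which every
    point-mass starting context has max-norm distance to the stationary
    distribution below ``tolerance`` (the O(mu^i) geometric approach to
    stationarity).
    """
    mat = model.context_matrix()
    if model.order == 0:
        return SpectralDiagnostics(0.0, np.ones(1), 0)
    v = stationary_distribution(model)
    mags = np.sort(np.abs(np.linalg.eigvals(mat)))[::-1]
    mu = float(mags[1]) if mags.size > 1 else 0.0
    # iterate all point-mass starts at once
    dist = np.eye(mat.shape[0])
    horizon = 0
    while np.max(np.abs(dist - v[None, :])) > tolerance and horizon < 10_000:
        dist = dist @ mat
        horizon += 1
    return SpectralDiagnostics(mu, v, horizon)


def marginal_profile(model, start=None, length: int | None = None) -> np.ndarray:
    """Per-position symbol distributions (rows i = d .. length, plus the
    start word's symbol marginal at row 0 .. d-1 folded into row d-1).

    Returns an array of shape (length, |A|) whose row i-1 is the
    distribution of the symbol at position i.  For i <= d the rows come
    from the start distribution over context words; later rows are
    obtained by pushing the context distribution through pi (or pi_i).
    """
    n = len(model.alphabet)
    d = model.order
    if isinstance(model, HeterogeneousModel):
        length = model.length if length is None else length
        if length > model.length:
            raise ModelError("length beyond model support")
    elif length is None:
        raise ModelError("length required for homogeneous models")
    if length < d:
        raise ModelError(f"length {length} < order {d}")
    mu = np.asarray(start) if start is not None else model.start_word_distribution()
    contexts = context_words(n, d)
    out = np.zeros((length, n))
    # positions 1..d from the start word distribution
    for i, w in enumerate(contexts):
        for k, b in enumerate(w):
            out[k, b] += mu[i]
    ctx_dist = mu.copy()
    if d == 0:
        ctx_dist = np.ones(1)
    ctx_index = {w: i for i, w in enumerate(contexts)}
    for pos in range(d + 1, length + 1):
        i = pos - d  # 1-based transition index
        table = model.table_at(i) if isinstance(model, HeterogeneousModel) else model.trans
        nxt = np.zeros(n**d)
        sym = np.zeros(n)
        for ci, w in enumerate(contexts):
            if ctx_dist[ci] == 0:
                continue
            for b in range(n):
                p = ctx_dist[ci] * table[ci, b]
                sym[b] += p
                if d > 0:
                    nxt[ctx_index[w[1:] + (b,)]] += p
        out[pos - 1] = sym
        ctx_dist = nxt if d > 0 else ctx_dist
    return out


def simulate(model, lengths, starts=None, seed=None, rng=None) -> list[list[int]]:
    """Draw independent sequences from the model.

    ``starts``: None (use the model's start distribution), a length-d
    word applied to every sequence, or a list of per-sequence length-d
    words.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(model.alphabet)
    d = model.order
    contexts = context_words(n, d)
    ctx_index = {w: i for i, w in enumerate(contexts)}
    if starts is not None and not isinstance(starts, (list, tuple)):
        raise ModelError("starts must be a word or list of words")
    per_seq_words = None
    if starts is not None:
        if starts and isinstance(starts[0], (list, tuple, str)):
            per_seq_words = list(starts)
        else:
            per_seq_words = [starts] * len(lengths)
    out = []
    for j, ell in enumerate(lengths):
        if ell < d:
            raise ModelError(f"sequence length {ell} < order {d}")
        if per_seq_words is not None:
            w = per_seq_words[j]
            w = tuple(
                model.alphabet.index(b) if isinstance(b, str) else int(b) for b in w
            )
            if len(w) != d:
                raise ModelError(f"start word {w} is not of length d={d}")
            seq = list(w)
        else:
            mu = model.start_word_distribution()
            seq = list(contexts[rng.choice(len(contexts), p=mu)])
        for pos in range(d + 1, ell + 1):
            i = pos - d
            table = (
                model.table_at(i)
                if isinstance(model, HeterogeneousModel)
                else model.trans
            )
            ctx = ctx_index[tuple(seq[-d:])] if d > 0 else 0
            seq.append(int(rng.choice(n, p=table[ctx])))
        out.append(seq)
    return out


# ---------------------------------------------------------------------------
# model file round-trip (JSON)
# ---------------------------------------------------------------------------

def model_to_json(model) -> str:
    doc = {
        "alphabet": list(model.alphabet.symbols),
        "order": model.order,
        "start": model.start_word_distribution().tolist()
        if (not isinstance(model, HomogeneousModel) or model.start is not None)
        else None,
        "kind": "heterogeneous" if isinstance(model, HeterogeneousModel) else "homogeneous",
        "transitions": model.trans.tolist(),
    }
    return json.dumps(doc, indent=1)


def model_from_json(text: str):
    doc = json.loads(text)
    alphabet = make_alphabet(doc["alphabet"])
    order = int(doc["order"])
    trans = np.array(doc["transitions"], dtype=float)
    start = np.array(doc["start"], dtype=float) if doc.get("start") is not None else None
    if doc.get("kind") == "heterogeneous":
        return HeterogeneousModel(alphabet=alphabet, order=order, trans=trans, start=start)
    return HomogeneousModel(alphabet=alphabet, order=order, trans=trans, start=start)
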