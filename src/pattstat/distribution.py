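"""Exact distribution of pattern counts via truncated generating functions.

The moment generating function of the count N_l in one sequence is
G(y) = m_d (P + yQ)^(l-d) 1^T; for a set of r independent sequences the
MGF of N = N_1 + ... + N_r is the product of the per-sequence MGFs.
All polynomial arithmetic is carried out in :class:`TruncPoly`:
coefficients of degree >= n_top are folded into a saturating top bucket,
so the bucket equals the exact upper-tail mass P(N >= n_top).  This is
what makes extreme tails (1e-167 and below) representable in plain
double precision: every term is a non-negative probability, sums never
cancel, and nothing is ever computed as 1 - CDF.

Three routes compute the set MGF:

* :func:`algorithm1` — position-wise products, one pass over all
  sequences, supports heterogeneous models, never forms an explicit
  r-fold convolution; O(l * n * |A| * L) time.
* :func:`algorithm2` — homogeneous models only; recycles the vector
  E(y)^T = (P + yQ)^m 1^T across sequences sorted by length, so the
  sweep costs O(l_max * n * |A| * L) regardless of r.
* :func:`algorithm3` — homogeneous, low pattern complexity: precomputes
  (P + yQ)^(2^k) and advances each sequence by binary decomposition of
  its length gap; O(K L^3 n^2) with K = log2 of the largest gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddedChain, start_vector

ALG3_L_GUARD = 512


class DistributionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# truncated polynomials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncPoly:
    """Polynomial in y with non-negative coefficients and saturating top.

    ``c[k]`` is the coefficient of y^k for k < n_top; ``c[n_top]``
    absorbs all mass of degree >= n_top.
    """

    c: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))

    @staticmethod
    def one(n_top: int) -> "TruncPoly":
        c = np.zeros(n_top + 1)
        c[0] = 1.0
        return TruncPoly(c)

    @staticmethod
    def from_coeffs(coeffs, n_top: int) -> "TruncPoly":
        coeffs = np.asarray(coeffs, dtype=float)
        c = np.zeros(n_top + 1)
        k = min(len(coeffs), n_top)
        c[:k] = coeffs[:k]
        c[n_top] = coeffs[n_top:].sum()
        return TruncPoly(c)

    @property
    def n_top(self) -> int:
        return len(self.c) - 1

    def total(self) -> float:
        return float(self.c.sum())

    def __mul__(self, other: "TruncPoly") -> "TruncPoly":
        return poly_mul(self, other)

    def mean(self) -> float:
        """Derivative at y = 1 (exact only when the top bucket is empty)."""
        return float(np.arange(len(self.c)) @ self.c)


def poly_mul(a: TruncPoly, b: TruncPoly) -> TruncPoly:
    """Truncated product: degrees >= n_top fold into the top bucket."""
    if a.n_top != b.n_top:
        raise DistributionError("polynomial truncation degrees differ")
    n_top = a.n_top
    full = np.convolve(a.c, b.c)
    c = np.zeros(n_top + 1)
    c[:n_top] = full[:n_top]
    c[n_top] = full[n_top:].sum()
    return TruncPoly(c)


def _shift_fold(M: np.ndarray) -> np.ndarray:
    """Multiply a coefficient-array (..., n_top+1) by y, saturating."""
    out = np.zeros_like(M)
    n_top = M.shape[-1] - 1
    if n_top == 0:
        out[..., 0] = M[..., 0]
        return out
    out[..., 1:n_top] = M[..., 0 : n_top - 1]
    out[..., n_top] = M[..., n_top - 1] + M[..., n_top]
    return out


def _start_poly(chain: EmbeddedChain, start, n_top: int) -> np.ndarray:
    """Start vector as an (L, n_top+1) polynomial array.

    Mass on a final state already carries one occurrence (a pattern
    word of length exactly d ending at position d), hence degree 1.
    """
    m, _ = start_vector(chain, start)
    V = np.zeros((chain.L, n_top + 1))
    deg1 = chain.final_mask & (m > 0)
    V[~deg1, 0] = m[~deg1]
    if n_top >= 1:
        V[deg1, 1] = m[deg1]
    else:
        V[deg1, 0] = m[deg1]
    return V


def _row_step(V: np.ndarray, PT, QT) -> np.ndarray:
    """One transition of the row polynomial vector: V <- V (P + yQ)."""
    return PT @ V + _shift_fold(QT @ V)


def _col_step(E: np.ndarray, P, Q) -> np.ndarray:
    """One transition of the column polynomial vector: E <- (P + yQ) E."""
    return P @ E + _shift_fold(Q @ E)


def mgf_single(chain: EmbeddedChain, start, length: int, n_top: int) -> TruncPoly:
    """MGF of the count in one sequence: m_d (P + yQ)^(l-d) 1^T.

    Heterogeneous chains use the position-indexed matrices; the cost is
    (l - d) sparse products of O(n_top * |A| * L) each.
    """
    d = chain.dfa.order
    if length < d:
        raise DistributionError(f"sequence length {length} < order {d}")
    V = _start_poly(chain, start, n_top)
    if chain.homogeneous:
        PT, QT = chain.P.T.tocsr(), chain.Q.T.tocsr()
        for _ in range(length - d):
            V = _row_step(V, PT, QT)
    else:
        for i in range(1, length - d + 1):
            P, Q = chain.matrices_at(i)
            V = _row_step(V, P.T.tocsr(), Q.T.tocsr())
    return TruncPoly(V.sum(axis=0))


def algorithm1(chains, starts, lengths, n_top: int) -> TruncPoly:
    """Single-pass set MGF; the only route for heterogeneous models.

    ``chains`` is one EmbeddedChain per sequence (homogeneous chains are
    treated as degenerate heterogeneous ones); all must share one DFA.
    The state-polynomial vector is collapsed to a scalar polynomial at
    every sequence boundary and re-expanded with the next start vector —
    no r-fold convolution of per-sequence distributions is ever formed.
    """
    chains = list(chains)
    if not (len(chains) == len(starts) == len(lengths)):
        raise DistributionError("chains, starts and lengths must align")
    dfa = chains[0].dfa
    if any(c.dfa is not dfa for c in chains[1:]):
        raise DistributionError("all sequences must share a single DFA")
    d = dfa.order
    G = TruncPoly.one(n_top)
    for chain, start, ell in zip(chains, starts, lengths):
        if ell < d:
            raise DistributionError(f"sequence length {ell} < order {d}")
        M = _start_poly(chain, start, n_top)
        # re-expand the collapsed scalar with the new start vector
        V = np.stack([np.convolve(G.c, M[q])[: n_top + 1] for q in range(chain.L)])
        # overflow of the convolution folds into the bucket
        tail_extra = np.array(
            [np.convolve(G.c, M[q])[n_top + 1 :].sum() for q in range(chain.L)]
        )
        V[:, n_top] += tail_extra
        if chain.homogeneous:
            PT, QT = chain.P.T.tocsr(), chain.Q.T.tocsr()
            for _ in range(ell - d):
                V = _row_step(V, PT, QT)
        else:
            for i in range(1, ell - d + 1):
                P, Q = chain.matrices_at(i)
                V = _row_step(V, P.T.tocsr(), Q.T.tocsr())
        G = TruncPoly(V.sum(axis=0))
    return G


def _require_homogeneous(chain: EmbeddedChain, name: str) -> None:
    if not chain.homogeneous:
        raise DistributionError(
            f"{name} requires a homogeneous model; use algorithm1 for "
            "heterogeneous models"
        )


def algorithm2(chain: EmbeddedChain, starts, lengths, n_top: int):
    """Homogeneous set MGF recycling E(y)^T = (P + yQ)^m 1^T.

    Sequences are processed in ascending length order (a stable sort;
    the per-sequence MGFs are returned in the input order); ties share
    the same E(y) snapshot.  Returns (G_N, [G_j ...]).
    """
    _require_homogeneous(chain, "algorithm2")
    d = chain.dfa.order
    r = len(lengths)
    order_idx = sorted(range(r), key=lambda j: lengths[j])
    E = np.zeros((chain.L, n_top + 1))
    E[:, 0] = 1.0
    m_polys = [_start_poly(chain, starts[j], n_top) for j in range(r)]
    per_seq: list = [None] * r
    U = TruncPoly.one(n_top)
    steps_done = 0
    for j in order_idx:
        target = lengths[j] - d
        if target < 0:
            raise DistributionError(f"sequence length {lengths[j]} < order {d}")
        while steps_done < target:
            E = _col_step(E, chain.P, chain.Q)
            steps_done += 1
        Gj = TruncPoly.from_coeffs(
            sum(np.convolve(m_polys[j][q], E[q]) for q in range(chain.L)), n_top
        )
        per_seq[j] = Gj
        U = poly_mul(U, Gj)
    return U, per_seq


def _poly_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Product of (L, L, n_top+1) polynomial matrices with saturation."""
    L, _, K = A.shape
    out = np.zeros((L, L, K))
    n_top = K - 1
    for a in range(K):
        Aa = A[:, :, a]
        for b in range(K):
            deg = min(a + b, n_top)
            out[:, :, deg] += Aa @ B[:, :, b]
    return out


def _poly_matvec(A: np.ndarray, E: np.ndarray) -> np.ndarray:
    """(L, L, K) polynomial matrix times (L, K) polynomial column vector."""
    L, _, K = A.shape
    out = np.zeros((L, K))
    n_top = K - 1
    for a in range(K):
        Aa = A[:, :, a]
        for b in range(K):
            deg = min(a + b, n_top)
            out[:, deg] += Aa @ E[:, b]
    return out


def algorithm3(chain: EmbeddedChain, starts, lengths, n_top: int, l_guard: int = ALG3_L_GUARD):
    """Homogeneous set MGF via binary powers of (P + yQ).

    Precomputes T^(2^k)(y) for k = 0..K with K the log2 of the largest
    length gap, then advances E(y)^T by the binary decomposition of each
    gap.  Space O(n K L^2), time O(n^2 K L^3): refused for patterns of
    high complexity (L above ``l_guard``), where algorithm2 is the
    appropriate route.
    """
    _require_homogeneous(chain, "algorithm3")
    if chain.L > l_guard:
        raise DistributionError(
            f"pattern complexity L={chain.L} exceeds the algorithm3 guard "
            f"({l_guard}): cubic cost in L is not suitable for a pattern of "
            "high complexity; use algorithm2"
        )
    d = chain.dfa.order
    r = len(lengths)
    order_idx = sorted(range(r), key=lambda j: lengths[j])
    sorted_lengths = [lengths[j] - d for j in order_idx]
    if any(m < 0 for m in sorted_lengths):
        raise DistributionError(f"sequence shorter than order {d}")
    gaps = [sorted_lengths[0]] + [
        sorted_lengths[k] - sorted_lengths[k - 1] for k in range(1, r)
    ]
    max_gap = max(gaps) if gaps else 0
    K_pow = max(0, int(max_gap).bit_length() - 1)
    L = chain.L
    T1 = np.zeros((L, L, n_top + 1))
    T1[:, :, 0] = chain.P.toarray()
    T1 += _shift_fold(
        np.concatenate(
            [chain.Q.toarray()[:, :, None], np.zeros((L, L, n_top))], axis=2
        )
    )
    powers = [T1]
    for _ in range(K_pow):
        powers.append(_poly_matmul(powers[-1], powers[-1]))

    E = np.zeros((L, n_top + 1))
    E[:, 0] = 1.0
    m_polys = [_start_poly(chain, starts[j], n_top) for j in range(r)]
    per_seq: list = [None] * r
    U = TruncPoly.one(n_top)
    for pos, j in enumerate(order_idx):
        gap = gaps[pos]
        k = 0
        while gap:
            if gap & 1:
                E = _poly_matvec(powers[k], E)
            gap >>= 1
            k += 1
        Gj = TruncPoly.from_coeffs(
            sum(np.convolve(m_polys[j][q], E[q]) for q in range(L)), n_top
        )
        per_seq[j] = Gj
        U = poly_mul(U, Gj)
    return U, per_seq


def select_algorithm(chain: EmbeddedChain, lengths) -> str:
    """Mirror of the complexity trade-offs: heterogeneous -> alg1;
    homogeneous with moderate lengths or high L -> alg2; else alg3."""
    if not chain.homogeneous:
        return "alg1"
    if max(lengths) <= 10_000 or chain.L > ALG3_L_GUARD:
        return "alg2"
    return "alg3"


def compute_set_mgf(chain: EmbeddedChain, starts, lengths, n_top: int, algorithm: str = "auto"):
    """Dispatch to one of the three algorithms; returns the set MGF."""
    if algorithm == "auto":
        algorithm = select_algorithm(chain, lengths)
    if algorithm == "alg1":
        return algorithm1([chain] * len(lengths), starts, lengths, n_top), algorithm
    if algorithm == "alg2":
        return algorithm2(chain, starts, lengths, n_top)[0], algorithm
    if algorithm == "alg3":
        return algorithm3(chain, starts, lengths, n_top)[0], algorithm
    raise DistributionError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# count distributions and tail P-values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountDistribution:
    """P(N = k) for k < n_top plus the exact tail mass P(N >= n_top)."""

    probs: np.ndarray  # k = 0 .. n_top - 1
    tail: float
    n_observed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_top(self) -> int:
        return len(self.probs)

    def total(self) -> float:
        return float(self.probs.sum() + self.tail)

    @staticmethod
    def from_mgf(mgf: TruncPoly, n_observed=None, **meta) -> "CountDistribution":
        return CountDistribution(
            probs=mgf.c[:-1].copy(),
            tail=float(mgf.c[-1]),
            n_observed=n_observed,
            meta=dict(meta),
        )


def tail_pvalues(dist: CountDistribution, n: int) -> tuple[float, float]:
    """(P(N <= n), P(N >= n)), both by direct summation of exact terms."""
    if n < 0:
        raise DistributionError("observed count must be >= 0")
    if n > dist.n_top - 1:
        raise DistributionError(
            f"observed count n={n} not exactly resolved at truncation "
            f"n_top={dist.n_top}; recompute the distribution with larger n_top"
        )
    p_le = float(dist.probs[: n + 1].sum())
    p_ge = float(dist.probs[n:].sum() + dist.tail)
    return p_le, p_ge


def expected_count(chain: EmbeddedChain, starts, lengths) -> float:
    """E[N] = sum over sequences and positions of P(Y_i in F).

    Computed by pushing each start vector through P + Q and summing the
    mass entering final states (plus any initial-occurrence mass).
    """
    d = chain.dfa.order
    total = 0.0
    for start, ell in zip(starts, lengths):
        m, _ = start_vector(chain, start)
        total += float(m[chain.final_mask].sum())
        v = m
        for i in range(1, ell - d + 1):
            P, Q = chain.matrices_at(i)
            vq = v @ Q
            total += float(vq.sum())
            v = v @ P + vq
    return total
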