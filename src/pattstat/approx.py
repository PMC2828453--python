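"""Single-sequence (concatenation) approximation and edge-effect reports.

Instead of the exact distribution of N = N_1 + ... + N_r over a set of
sequences, one may compute the distribution of N', the count in a
single sequence of adjusted length l' = sum(l_j) - (r-1) * offset.  The
offset removes concatenation positions where no genuine occurrence
could lie (h - 1 for a pattern of fixed word length h; no canonical
choice exists for variable-length patterns).  The approximation is
subject to two edge effects — forbidden overlap positions and the
stationarity assumption — whose direction is not predictable in
general; this module quantifies them against the exact computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distribution import CountDistribution, mgf_single, tail_pvalues
from .embedding import EmbeddedChain
from .markov import stationary_distribution
from .patterns import PatternExpr

NO_CANONICAL_OFFSET = None


class ApproxError(ValueError):
    pass


def default_offset(expr: PatternExpr):
    """h - 1 for a fixed-length pattern, else None (no canonical choice)."""
    h = expr.fixed_len()
    return None if h is None else h - 1


def adjusted_length(lengths, offset: int) -> int:
    """l' = sum(l_j) - (r - 1) * offset; must stay positive."""
    lp = int(sum(lengths)) - (len(lengths) - 1) * int(offset)
    if lp <= 0:
        raise ApproxError(f"adjusted length {lp} <= 0 for offset {offset}")
    return lp


def _start_distribution(chain: EmbeddedChain, mode, starts=None) -> object:
    if isinstance(mode, (list, tuple, np.ndarray)) or (
        isinstance(mode, str) and mode not in ("stationary", "empirical")
    ):
        return mode  # fixed word or explicit distribution
    if mode == "stationary":
        return stationary_distribution(chain.model)
    if mode == "empirical":
        return chain.model.start_word_distribution()
    raise ApproxError(f"unknown start mode {mode!r}")


def approx_distribution(
    chain: EmbeddedChain,
    lengths,
    offset: int,
    start="stationary",
    n_top: int = 1,
) -> CountDistribution:
    """Exact distribution of N' on one sequence of adjusted length.

    ``start`` is 'stationary' (default), 'empirical' (the model's
    fitted starting distribution) or a fixed length-d word.  Undefined
    for heterogeneous models.
    """
    if not chain.homogeneous:
        raise ApproxError(
            "the single-sequence approximation is only defined for "
            "homogeneous models"
        )
    lp = adjusted_length(lengths, offset)
    if lp <= chain.dfa.order:
        raise ApproxError(f"adjusted length {lp} <= order {chain.dfa.order}")
    mgf = mgf_single(chain, _start_distribution(chain, start), lp, n_top)
    return CountDistribution.from_mgf(mgf, offset=offset, adjusted_length=lp)


@dataclass(frozen=True)
class ApproxComparison:
    n: int
    exact_p_ge: float
    offset: int
    start_mode: object
    approx_p_ge: float

    @property
    def ratio(self) -> float:
        return self.approx_p_ge / self.exact_p_ge

    @property
    def log10_diff(self) -> float:
        return float(np.log10(self.approx_p_ge) - np.log10(self.exact_p_ge))


def compare_to_exact(
    chain: EmbeddedChain,
    lengths,
    n: int,
    exact_p_ge: float,
    offsets,
    start_modes=("stationary",),
) -> list[ApproxComparison]:
    """Side-by-side exact vs approximate upper-tail P-values.

    One row per (offset, start mode) combination, mirroring the
    structure of edge-effect study tables.
    """
    rows = []
    for offset in offsets:
        for mode in start_modes:
            dist = approx_distribution(chain, lengths, offset, mode, n_top=n + 1)
            _, p_ge = tail_pvalues(dist, n)
            rows.append(
                ApproxComparison(
                    n=n,
                    exact_p_ge=exact_p_ge,
                    offset=offset,
                    start_mode=mode,
                    approx_p_ge=p_ge,
                )
            )
    return rows
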