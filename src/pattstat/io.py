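"""File formats and the end-to-end pipeline.

FASTA input goes through Biopython; pattern files are plain text (one
pattern per line, ``#`` comments, dialect chosen per file); models
round-trip through JSON (see :mod:`pattstat.markov`); results come out
as a TSV with 3-significant-digit scientific P-values plus
full-precision machine columns.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import Alphabet, AlphabetError, make_alphabet
from .automaton import compile_dfa, scan
from .distribution import (
    CountDistribution,
    compute_set_mgf,
    expected_count,
    tail_pvalues,
)
from .embedding import embed, embed_heterogeneous
from .markov import (
    HeterogeneousModel,
    fit_heterogeneous_window,
    fit_homogeneous,
    model_from_json,
)
from .patterns import parse_pattern


class IOError_(ValueError):
    pass


def read_fasta(path, alphabet) -> list[tuple[str, list[int]]]:
    """Read FASTA records and tokenize against the alphabet.

    Order-preserving; a token that cannot be resolved (longest match)
    is a hard error naming the record.
    """
    alphabet = make_alphabet(alphabet)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append((rec.id, alphabet.tokenize(str(rec.seq))))
        except AlphabetError as e:
            raise IOError_(f"record {rec.id!r}: {e}") from None
    return out


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_patterns(path) -> list[str]:
    """One pattern per line; '#' comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def format_pvalue(p: float) -> str:
    """Scientific notation with 3 significant digits (table style)."""
    return f"{p:.2e}"


@dataclass
class RunConfig:
    """Everything needed to reproduce an exact-pipeline run."""

    alphabet: object  # name or token list
    patterns: list  # pattern strings
    dialect: str = "words"
    sequences: list = None  # list of (id, token-index list); or use fasta_path
    fasta_path: str | None = None
    model_source: str = "fit-homogeneous"  # or fit-heterogeneous / model-file
    model_path: str | None = None
    order: int = 1
    window: int = 200
    pseudocount: float = 0.0
    algorithm: str = "auto"

    def load_sequences(self, alphabet):
        if self.sequences is not None:
            return self.sequences
        if self.fasta_path is None:
            raise IOError_("config needs sequences or a FASTA path")
        return read_fasta(self.fasta_path, alphabet)

    def load_model(self, seqs, alphabet):
        raw = [s for _, s in seqs]
        if self.model_source == "fit-homogeneous":
            return fit_homogeneous(raw, alphabet, self.order, self.pseudocount)
        if self.model_source == "fit-heterogeneous":
            return fit_heterogeneous_window(raw, alphabet, self.order, self.window)
        if self.model_source == "model-file":
            return model_from_json(Path(self.model_path).read_text())
        raise IOError_(f"unknown model source {self.model_source!r}")


RESULT_COLUMNS = [
    "pattern", "dialect", "L", "n", "expected", "p_le", "p_ge",
    "algorithm", "n_top", "p_le_full", "p_ge_full",
]


def run_exact(config: RunConfig) -> list[dict]:
    """Full pipeline: parse, compile, fit, scan, compute, report.

    One result row per pattern: observed count n (matching positions,
    1-based ends, overlaps counted), expectation, both tail P-values at
    truncation n_top = n + 1, the DFA size L and the algorithm used.
    Deterministic given the config.
    """
    alphabet = make_alphabet(config.alphabet)
    seqs = config.load_sequences(alphabet)
    model = config.load_model(seqs, alphabet)
    heterogeneous = isinstance(model, HeterogeneousModel)
    rows = []
    for pat in config.patterns:
        expr = parse_pattern(pat, config.dialect, alphabet)
        dfa = compile_dfa(expr, alphabet, config.order)
        counts = [scan(dfa, s)[0] for _, s in seqs]
        n = int(sum(counts))
        lengths = [len(s) for _, s in seqs]
        d = config.order
        if heterogeneous:
            chain = embed_heterogeneous(dfa, model)
        else:
            chain = embed(dfa, model)
        starts = [tuple(s[:d]) if d > 0 else () for _, s in seqs]
        n_top = n + 1
        mgf, used = compute_set_mgf(chain, starts, lengths, n_top, config.algorithm)
        dist = CountDistribution.from_mgf(mgf, n_observed=n)
        p_le, p_ge = tail_pvalues(dist, n)
        rows.append(
            {
                "pattern": pat,
                "dialect": config.dialect,
                "L": dfa.n_states,
                "n": n,
                "expected": expected_count(chain, starts, lengths),
                "p_le": format_pvalue(p_le),
                "p_ge": format_pvalue(p_ge),
                "algorithm": used,
                "n_top": n_top,
                "p_le_full": repr(p_le),
                "p_ge_full": repr(p_ge),
            }
        )
    return rows


def results_to_tsv(rows) -> str:
    buf = _io.StringIO()
    buf.write("\t".join(RESULT_COLUMNS) + "\n")
    for row in rows:
        buf.write("\t".join(str(row[c]) for c in RESULT_COLUMNS) + "\n")
    return buf.getvalue()


def distribution_to_tsv(dist: CountDistribution) -> str:
    lines = ["k\tprob"]
    for k, p in enumerate(dist.probs):
        lines.append(f"{k}\t{float(p)!r}")
    lines.append(f">={dist.n_top}\t{float(dist.tail)!r}")
    return "\n".join(lines) + "\n"
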