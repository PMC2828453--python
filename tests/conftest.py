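"""Shared fixtures: the worked binary-alphabet example and helpers.

The worked example: pattern {abab, abaab, abbab} over {a, b}, three
observed sequences with 2 + 1 + 1 occurrences, and an order-1
homogeneous source with pi(a,b) = 0.3, pi(b,a) = 0.4 started from the
observed first letters (a, b, a) with lengths (9, 6, 8).
"""

import numpy as np
import pytest

from pattstat import (
    HomogeneousModel,
    compile_dfa,
    embed,
    make_alphabet,
    parse_words,
)

TOY_WORDS = ["abab", "abaab", "abbab"]
TOY_TRANS = np.array([[0.7, 0.3], [0.4, 0.6]])
TOY_LENGTHS = [9, 6, 8]
TOY_STARTS = ["a", "b", "a"]
# observed sequences: 2 occurrences ending at 5 and 8; 1 at 5; 1 at 8
TOY_SEQS = ["abaabbaba", "bababa", "abbaabab"]

TOY_G1 = [0.743104, 0.208944, 0.0450490, 0.0029030]
TOY_G2 = [0.94816, 0.05184]
TOY_G3 = [0.7761376, 0.1880064, 0.0353376, 0.0005184]


@pytest.fixture(scope="session")
def ab2():
    return make_alphabet(["a", "b"])


@pytest.fixture(scope="session")
def toy_expr(ab2):
    return parse_words(TOY_WORDS, ab2)


@pytest.fixture(scope="session")
def toy_dfa(ab2, toy_expr):
    return compile_dfa(toy_expr, ab2, 1)


@pytest.fixture(scope="session")
def toy_model(ab2):
    return HomogeneousModel(
        alphabet=ab2, order=1, trans=TOY_TRANS, start=np.array([2 / 3, 1 / 3])
    )


@pytest.fixture(scope="session")
def toy_chain(toy_dfa, toy_model):
    return embed(toy_dfa, toy_model)
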