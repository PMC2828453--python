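#!/usr/bin/env python
"""Long-running stress case: compile the APPLE domain signature.

The APPLE (PS00495) regular expression is the largest signature in the
PROSITE collection by automaton size: at order 1 over the 20-letter
amino-acid alphabet its minimal non-1-ambiguous DFA has 837,507 states.
Compiling it exercises the subset construction, disambiguation and
minimization at scale.  Expect a run of roughly ten minutes and
several GiB of memory; this is deliberately not in the test suite.

Usage:  python scripts/stress_apple.py
"""

import time

from pattstat import compile_dfa, make_alphabet, parse_prosite

APPLE = (
    "C-x(3)-[LIVMFY]-x(5)-[LIVMFY]-x(3)-[DENQ]-[LIVMFY]-x(10)-C-x(3)-C-T-"
    "x(4)-C-x-[LIVMFY]-F-x-[FY]-x(13,14)-C-x-[LIVMFY]-[RK]-x-[ST]-"
    "x(14,15)-S-G-x-[ST]-[LIVMFY]-x(2)-C"
)

EXPECTED_STATES = 837_507


def main() -> None:
    protein = make_alphabet("protein")
    expr = parse_prosite(APPLE, protein)
    t0 = time.time()
    dfa = compile_dfa(expr, protein, order=1)
    dt = time.time() - t0
    print(f"APPLE automaton: L = {dfa.n_states} states ({dt:.1f} s)")
    print(f"expected: {EXPECTED_STATES}")
    assert dfa.n_states == EXPECTED_STATES, "state count mismatch"


if __name__ == "__main__":
    main()
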