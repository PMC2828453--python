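"""Automaton sizes for protein signatures of increasing complexity.

Parses a few PROSITE-syntax signatures, compiles each into its minimal
non-1-ambiguous automaton over the 20 amino acids, and reports the
pattern complexity L — the quantity that governs the running time and
memory of every exact computation downstream.
"""

from pattstat import compile_dfa, make_alphabet, parse_prosite

protein = make_alphabet("protein")

signatures = {
    "RGD (cell adhesion tripeptide)": "R-G-D",
    "short class pattern": "[KRQ]-[LIVMA]-x(2)",
    "range repetition": "C-x(2,4)-C",
    "mixed classes": "[ST]-G-x-[ST]-[LIVMFY]-x(2)-C",
}

for name, sig in signatures.items():
    expr = parse_prosite(sig, protein)
    dfa = compile_dfa(expr, protein, order=1)
    words = expr.n_words_bound()
    print(f"{name:35s} {sig:25s} L = {dfa.n_states:5d}  (<= {words} words)")

# L is not predictable from the signature length alone: classes and
# range repetitions can blow the automaton up or leave it small.  The
# exact P-value algorithms cost O(total_length * n * |A| * L), so L is
# the number to check before launching a large computation.
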