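# Methods

## Model

Sequences X₁…X_ℓ are drawn from an order-d Markov source over a finite
alphabet 𝒜 (|𝒜| ≥ 2), specified by a starting distribution μ₁ over
length-d words and transition probabilities π(w, b) from context w to
symbol b.  Homogeneous models use one transition table; heterogeneous
models use one table per position i (the table at index i governs the
symbol at position i + d).  A pattern denotes a finite, non-empty set
of non-empty words; the statistic of interest is the number of
*matching positions* — position i counts once when some pattern word
is a suffix of X₁…X_i, so overlapping occurrences all count.  Words
shorter than d are rejected: occurrences that would complete inside
the initial context would require a more elaborate starting
distribution for the embedded chain, and no published rule pins it
down.  Words of length exactly d are allowed; the occurrence at
position d is carried by tagging start mass that lands on a final
state with one occurrence.

## Automaton construction

The compiler produces the minimal non-d-ambiguous DFA for 𝒜*·𝒲:

1. bounded repetitions are rewritten into concatenations of optional
   copies, and a Glushkov position automaton is built (epsilon-free;
   positions carry symbol classes, so degenerate codes and PROSITE
   classes never get expanded into words);
2. subset construction over position sets, with a fresh match attempt
   admitted at every text position — this realizes the 𝒜* prefix and
   keeps the automaton complete;
3. product with a register of the last d symbols read, so each state
   reachable by a length ≥ d text knows its history (states reachable
   only by shorter texts keep an undefined history);
4. Moore partition refinement whose initial partition separates
   (finality, history): plain minimization could merge states with
   different histories and leave the per-state transition
   probabilities ill-defined;
5. a merge-and-verify pass that folds each undefined-history state
   into a language-equivalent history-carrying block when re-running
   the refinement confirms the quotient: for d = 1 this typically
   absorbs the start state (the RGD signature compiles to 22 states
   rather than 23 because of it);
6. canonical breadth-first relabeling from the start state in alphabet
   order, making compiled automata byte-reproducible.

Minimality within the non-d-ambiguous class is checked empirically
(tests attempt pairwise merges and verify language divergence), not
proven.

## Embedding and generating functions

For a non-d-ambiguous DFA the state process Yᵢ = δ(σ, X₁…Xᵢ) is an
order-1 chain on the L states.  Each kept state contributes |𝒜|
transitions weighted by π(history, b); transitions entering a final
state go to Q, the rest to P, so T = P + Q is row-stochastic on the
embedded support and Q's columns are exactly the final states.  States
with undefined history carry no probability mass and are dropped
(re-indexing recorded).  Matrices are CSR with at most |𝒜|·L
non-zeros, which is what the stated complexities assume.

The MGF of a single count is m_d (P + yQ)^{ℓ−d} 1ᵀ; the set MGF is the
product over sequences.  Coefficients live in truncated polynomials
with a saturating top bucket at degree n_top: degrees ≥ n_top fold
into the bucket, which therefore equals the exact tail mass
ℙ(N ≥ n_top).  The default n_top is n + 1 for observed count n.  The
alternative reading of the truncation operator — dropping high-degree
terms — was rejected because it loses the tail normalization that
makes ℙ(N ≥ n) a direct sum of non-negative doubles; saturation keeps
total mass 1 to 1e-12 on every instance (property-tested), and doubles
cover the extreme P-values of interest (down to ~1e-300) without
log-space arithmetic, since positive sums cannot cancel.

Routes: algorithm1 sweeps all positions of all sequences in one pass,
collapsing the state-polynomial vector to a scalar at sequence
boundaries and re-expanding with the next start vector — no explicit
convolution of per-sequence distributions.  algorithm2 (homogeneous
only) maintains E(y)ᵀ = (P + yQ)^m 1ᵀ, advancing m across sequences
sorted by length (stable sort; outputs restored to input order; ties
share the snapshot).  algorithm3 (homogeneous, L ≤ 512 by default)
precomputes (P + yQ)^(2^k) and advances by binary decomposition of
length gaps; it refuses high-complexity patterns because of its cubic
cost in L.  Auto-selection: heterogeneous → algorithm1; homogeneous
with max length ≤ 10⁴ or L > 512 → algorithm2; otherwise algorithm3.

Both tail P-values are direct summations (never 1 − CDF); the
expectation E[N] is computed by pushing start vectors through P + Q
and accumulating the mass entering final states, and is cross-checked
in tests against the MGF derivative and Monte-Carlo simulation.

## Fitting

Homogeneous MLE pools transition counts over all sequences; the
starting distribution is the empirical law of first-d words.  The
pseudocount default is 0 with a hard error on unseen contexts — a
silent uniform fill would shift P-values invisibly.  The sliding-window
heterogeneous estimator pools counts, across all (equal-length)
sequences, over transition positions inside a window of half-width
⌊w/2⌋ centered on the position and clipped at the sequence ends (no
wrapping, no shrink compensation); with w ≥ ℓ it reproduces the
homogeneous fit exactly (tested).  Pooling across sequences (rather
than averaging per-sequence estimates) is the chosen interpretation of
window fitting.

Spectral diagnostics work on the |𝒜|^d-context transition matrix:
dense eigendecomposition for the stationary distribution (residual
checked below 1e-10) and the second-eigenvalue magnitude μ, with
irreducibility/aperiodicity verified via the strongly-connected-
component structure (networkx).  The convergence horizon is the
smallest i at which every point-mass start is within a tolerance
(default 1e-15, i.e. machine precision) of stationarity in max norm —
the O(μ^i) rate makes this the quantity that predicts whether
single-sequence approximations are trustworthy.

## Single-sequence approximation

The concatenation approximation computes the exact law of N′ on one
sequence of length ℓ′ = Σℓⱼ − (r−1)·offset.  The canonical offset is
h − 1 for patterns whose words share length h; for variable-length
patterns there is no canonical choice and the API requires an explicit
value rather than defaulting.  Start modes: stationary (default),
empirical (the fitted μ₁), or a fixed length-d word.  The edge-effect
direction is not assumed — approximations can over- or under-shoot —
so the comparison report just lays exact and approximate P-values side
by side with ratio and log₁₀ difference.  One exact identity is tested:
with stationary start, fixed word length h and offset h − 1, E[N′]
equals the exact E[N] to 1e-10 (per-position occurrence probability is
constant under stationarity and the position counts match).

## Synthetic data and oracles

Random instances draw Dirichlet(1,…,1) transition rows (full support,
hence irreducible and aperiodic), random bounded word sets, and
fixed-word starts, all reproducible from a seed.  Two independent
oracles back every statistical claim: suffix-testing occurrence
counting (no automaton), and full enumeration of all sequence tuples
weighted by exact Markov probability (budget-guarded at 10⁷
evaluations; heterogeneous models supported).  Test problem sizes —
oracle instances with ℓⱼ ≤ 6, tri-algorithm sweeps with r ≤ 5 and
ℓⱼ ≤ 200, simulation checks at 10⁴–10⁵ draws — were chosen so the
enumeration stays inside its budget while covering saturation,
heterogeneity and near-absorbing rows.  What the generator does not
emulate: real compositional structure (codon bias, CpG islands),
unequal-length heterogeneous data sets, and alphabet sizes beyond 4 in
the enumeration-backed checks; agreement on these fixtures validates
the algebra, not the biological fit of any particular null model.

## Numerical choices and limitations

* All probability arithmetic is linear-scale double precision;
  coefficients are probabilities bounded by 1.
* Row-sum, normalization and residual tolerances: 1e-12 for stochastic
  rows and distribution masses, 1e-10 for stationarity residuals.
* The automaton pipeline is exact integer/set manipulation; no
  floating point enters before the embedding.
* PROSITE anchors `<`/`>` are rejected (counting occurrences at every
  position is incompatible with anchored semantics); unbounded
  repetitions are rejected (the language must be finite).
* Heterogeneous models must cover the longest sequence; positions
  beyond the support are errors, not extrapolations.
* algorithm3's guard (L ≤ 512) is configurable; above it the cubic
  cost in L dominates any saving from the logarithmic length
  dependence.
* Very large automata (hundreds of thousands of states) compile in
  pure Python with BFS/refinement passes vectorized in numpy; the largest
  PROSITE signature compiles in about nine minutes
  (`scripts/stress_apple.py`).
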