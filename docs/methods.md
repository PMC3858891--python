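# Methods

## Problem and model

Given a rooted tree G with n leaves, each leaf carrying a nonnegative
integer gene length (0 = gene absent from that genome), find an integer
label for every internal node minimising the summed edge cost

    φ(x, y) = 0 if x = y; C1 if x = 0; C2 if y = 0; θ(x, y) otherwise,

with `x` the parent-side and `y` the child-side label, gain penalty C1,
loss penalty C2, and length-change distance θ(x, y) = |x − y|^λ, λ ≥ 1.
θ satisfies the usual axioms (zero iff equal, symmetric, strictly
increasing as the arguments move apart), from which it follows that an
optimal labeling only ever uses labels in {0} ∪ [g_min, g_max], where
g_min/g_max bound the positive leaf labels; all solvers restrict their
domain accordingly, and a widened-domain enumeration check confirms the
restriction empirically.

Zero is "no value", not a short gene: an edge 0 → k is a gene birth
(cost C1), k → 0 a death (cost C2), and 0 → 0 costs nothing.  The modeling
convention C1 > C2 > m (m = g_max − g_min + 1) encodes that losses are more
plausible than gains and that either event outweighs any pure length
change.  Violating it leaves every algorithm in this package well defined
and still exact (see below), so `validate_penalties` warns rather than
errors; only the biological reading of the result suffers.

## Generic dynamic program (`sankoff`)

Classical Sankoff recursion over the label domain: σ_k(i) is the minimal
subtree cost with node k labeled i.  Leaves pin σ to their observation with
an infinite sentinel elsewhere; an internal node with children b sums, per
child, min(min_j [θ(i,j) + σ_b(j)], C2 + σ_b(0)) for positive i, and
min(σ_b(0), C1 + min_j σ_b(j)) for i = 0.  Arbitrary arity, any λ ≥ 1;
O(|V|·m²).  The traceback recomputes argmins from the stored table (O(m)
per edge) instead of keeping back-pointers.

Tie policy (all choices attain the same cost; fixed for determinism): at
the root a positive label is preferred over 0 on a tie and the smallest
optimal positive label is taken; below the root, positive is preferred on
ties under a positive parent and absence under an absent parent, and among
tied positive labels the one nearest the parent's label, then the
smallest, wins.

## Interval algorithm (`interval`)

For binary trees under the Manhattan distance the conditional-cost profile
σ_a(·) is piecewise linear with unit-bounded slopes once regularised, and
the classical idea is to summarise it by a quartet (left, right, Z, X): an
interval of equally cheap positive labels, the cost Z of labeling the node
0, and the cost X of any label in the interval.  Leaves start as
([p, p], C1 + C2, 0) when the gene is present and (undefined, 0, C1 + C2)
when absent — the finite sentinel keeps the recurrences uniform — and a
parent's displayed interval is the intersection of its children's
intervals, the gap between them when disjoint, or the defined child's
interval when only one is defined, with
Z(a) = min(Z(l), C1 + X(l)) + min(Z(r), C1 + X(r)).

The quartet alone is, however, a lossy summary.  Two failure modes were
isolated during development with randomized cross-checks against the DP
and a brute-force enumerator (both are frozen as regression tests):

1. **Narrowing must propagate.**  When the zero branch (C2 + Z of a child)
   strictly attains X(a), the flat region of σ_a is the surviving child's
   flat region, not the merged interval; a traceback-time-only interval
   correction cannot repair the parent's X, which has already consumed the
   too-wide interval in its gap term, and the reported minimum drifts below
   the true optimum.
2. **Profiles can be bimodal.**  A keep/drop crossover between the two
   children can give σ_a a second local minimum strictly between the flat
   value X and the cap C2 + Z (regression instance: minima 60 and 62 under
   cap 63, with C1 > C2 > m satisfied).  No single (interval, X) pair can
   price a parent edge against such a profile, in either direction.

The implementation therefore carries, per node, the exact envelope:
σ_a = h_l + h_r with h_c(i) = min(reach_c(i), C2 + Z(c)) and
reach_c(i) = min_j(|i − j| + σ_c(j)) the 1-Lipschitz regularisation of the
child profile, computed by a forward/backward distance transform in O(m).
X is the envelope minimum, the node's flat region its (first) argmin run,
and the quartet is derived from the envelope for reporting.  On every
instance where the quartet summary is faithful — in particular all the
small worked examples — the derived numbers coincide with the classical
recurrences; where it is not, the envelope is exact.  Total cost
min(Z(root), X(root)) always equals the DP optimum; this cross-algorithm
equivalence (plus a per-edge cost audit of every traceback) is the
package's primary correctness surface, exercised on hundreds of seeded
random instances per test run.  A pleasant side effect of the envelope is
that exactness no longer depends on C1 > C2 > m at all.

The correction predicate Ω(a) = (X(a) ≤ Z(a)) ∧ (X(l) > Z(l) ∨ X(r) > Z(r))
is exposed and tested as stated: it flags nodes whose displayed interval
may exceed the true flat region.  It is necessary but not sufficient — a
child may prefer absence in isolation while the parent's optimum keeps its
gene — so the shipped corrected intervals are read off the exact profiles
rather than recomputed by predicate-guarded intersections.  Consequently a
corrected interval is not always a subset of the displayed one (it is in
all the worked examples).

Traceback: the root takes 0 if Z < X, else a member of its flat region
chosen by a presentation-only policy (`smallest` by default, also
`largest`/`midpoint`; every member attains the same cost — e.g. the
four-leaf example ((125,141),(136,150)) admits any root label in
[136, 141]).  Each internal child takes 0 when the zero branch attains the
parent-side minimum (positive preferred on ties under a positive parent),
else the minimising positive label nearest the parent's.  Costs are
re-derived from the stored profiles so the scenario audit is bit-exact.

## Scenario and audit

A complete labeling induces one event per directed edge: gain, loss,
elongation/shortening (λ = 1) or plain "change" (λ ≠ 1), or none.  The
audited identity — scenario total = Σ|Δ| over doubly-positive edges +
k1·C1 + k2·C2 = the solver's reported minimum — is enforced after every
reconstruction; a mismatch raises (CLI exit code 3) because it would mean
an algorithmic defect, and with λ = 1 and integer penalties all arithmetic
is exact integer arithmetic.

## Paralog preprocessing

Genomes with several family copies are collapsed to one label: the median
copy length, using the lower median for even counts so the label is always
an observed length (the convention is ours; either choice stays within the
observed range).  Outlier flagging is report-only by default, since
fusion-protein-like outliers are normally excised by inspection: the
default rule is the modified z-score (0.6745·|x − median|/MAD > 3.5,
needing ≥ 3 values), with a pairwise-ratio fallback (larger value > 1.8×
the smaller) for two-copy genomes, and `--drop-outliers` to exclude
flagged values from the median.  On the shipped archaeal chemotaxis-family
table (COG0835) the MAD rule flags the 344- and 779-residue copies of
genome 50 and the ratio rule the 328-residue copy of genome 29, matching
what inspection removes.

## Brute-force oracle

`exhaustive_min` enumerates every assignment of {0} ∪ [g_min, g_max] to
the internal nodes by materialising the full cost tensor over the d^k
assignment grid with numpy broadcasting (d = domain size, k = internal
nodes), capped by grid size (default 10^7 entries; the acceptance suite
uses 2×10^7, which admits instances with up to 7 internal nodes at domain
width ≤ 11).  `widen` extends the domain for range-restriction checks.

## Synthetic data

`random_leaf_instance` draws instances for the equivalence suites: 2–16
leaves, each absent with probability 0.25 or uniform in an integer window
of width ≤ 10, penalties sampled to respect C1 > C2 > m.  These are the
conditions under which the cross-algorithm guarantees are exercised.

`simulate_instance` is a forward model with known ancestral truth: a
present gene is lost along an edge with probability 0.15, an absent one
gained with probability 0.05 (losses more likely than gains, matching the
penalty asymmetry), and a surviving gene drifts by a uniform integer step
of at most ±3 residues around a root length near 150.  It emulates
single-copy presence/absence and gradual length drift; it does not emulate
paralog families, horizontal transfer, branch-length-dependent rates or
realistic indel processes, so passing recovery tests show consistency of
the solvers with the model's own event semantics, not fidelity to real
protein evolution.  Reconstruction cost is checked against the parsimony
bound (never above the true history's cost).

## Numerical and degenerate-input choices

All-zero leaf tables are legal and short-circuit to the all-zero labeling
at cost 0.  Leaves missing from a length table default to 0 with a logged
warning (strict mode errors).  Branch lengths in Newick input are parsed
and ignored — the model is per-edge.  Child order is preserved but never
affects costs (tested).  λ is restricted to λ ≥ 1, with λ = 1 required by
the interval solver.  DP tables use float64 with an infinite sentinel;
integer inputs stay exact (integers below 2^53) and integral results are
reported as ints.

## Problem sizes

The default test run uses trees of up to 16 leaves, label windows of width
≤ 10, 200 instances in the main equivalence suite and 100 (×2 exponents)
in the arbitrary-arity suite, with the enumeration oracle applied to the
sub-instances within its grid cap; the whole suite completes in a few
seconds.  These sizes were chosen because every failure mode found during
development manifested well below them.

## Known limitations

The displayed quartet intervals follow the classical merge rule and are
reporting aids; on adversarial profiles the exact flat region deviates
from them.  The interval solver requires strictly binary trees and λ = 1
(the CLI directs other inputs to `--method dp`).  Scenario events are
parsimony assertions, not probabilistic statements; no attempt is made to
enumerate co-optimal scenarios beyond the optimal-root-label set.
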