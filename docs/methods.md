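# Methods

## Model

`ontosim` treats an ontology as a rooted DAG whose nodes are terms and
whose edges point from parent (more general) to child (more specific),
restricted to the `is_a` and `part_of` relations. Both relations are
treated identically everywhere except in the Wang comparator, which is the
only measure that weights them differently; the regulates family and
obsolete terms are dropped at parse time. The three GO namespaces (BP, MF,
CC) coexist as separate roots in one graph; roots are treated as
biologically uninformative (IC 0) and cross-namespace pairs score 0
because they share no ancestor.

### Topological position and information

The reachability measure of a term is

    mu(root) = 1,     mu(z) = prod over parents x of mu(x) / C(x),

with C(x) the child count of x, evaluated in topological order so parents
are always finished before children. Each parent contributes once: the
parent set is a set, so a parent reached along several paths is not
multiplied twice. The topological information is IC_T(z) = -ln mu(z), in
nats.

Consequences used throughout:

* IC_T never decreases from parent to child; equality happens exactly on
  an unbranched single-parent/single-child step. Maximal runs of such
  steps form **synonym classes** — terms with identical positions joined
  by a directed path — which the package materializes with a union-find
  over exact (alpha, beta) equality plus a reachability check. Exact
  float equality is the right test here: a synonym step multiplies by
  exactly 1/1, so equal positions along a path are bit-identical.
* The similarity S(x,y) = IC_T of the minimal-mu common self-inclusive
  ancestor divided by max(IC_T(x), IC_T(y)) lies in [0, 1]; d = 1 - S is
  symmetric, satisfies the triangle inequality (checked on ~10^4 sampled
  triples across 300 random DAGs in the test suite), and vanishes exactly
  within a synonym class.

The candidate ancestor set is the intersection of the two *self-inclusive*
ancestor sets. For a parent-child pair this set contains the parent, so
the score is IC(parent)/IC(child) — the published per-pair values on the
bundled subgraph confirm this reading; including both query terms
unconditionally would force every ancestor-descendant pair to score 1.

### Underflow-safe arithmetic

mu decays roughly like (branching factor)^-depth and underflows IEEE
doubles within a few hundred levels. Positions are therefore stored as
(alpha, beta) with mu = alpha * 10^beta, 0.1 <= alpha < 1 (alpha = 1 only
for mu = 1) and integer beta, renormalized after every multiplication;
IC_T = -ln(alpha) - beta ln 10 never materializes mu. The exponent is
exact; only the mantissa accumulates rounding, giving ~1e-15 relative
log-space error against an exact-rational oracle (the suite enforces
<= 1e-12 over 200 seeded DAGs). Ordering of positions compares
beta + log10(alpha), not the raw fields, so verbatim published mantissas
that are denormalized (e.g. `0.0456910e-27`) order correctly.

### Comparator measures

* **Wang**: S_z(t) propagates from z toward the root by max with factors
  0.8 (is_a) / 0.6 (part_of); IC_W(z) is the sum of S_z over z's
  self-inclusive ancestors, and the pair score is the usual shared-sum
  ratio. Only the ancestor-induced sub-DAG of z is materialized.
* **Zhang**: leaf path counts are summed bottom-up as exact integers;
  D(t) = count(t)/count(root) per root, IC_Z = -ln D, IC_Zu = IC_Z/ln N
  with N the term count under the term's root. Pair scores take the max
  over common self-inclusive ancestors, scaled either by IC_Zu
  (uniform Resnik) or Lin-style by 2*IC_Z(a)/(IC_Z(x)+IC_Z(y)).
* **Annotation frequency**: the maximum-likelihood estimator — distinct
  annotated proteins per term after true-path propagation, IC =
  -ln(freq(t)/freq(root)). The literature defines this family without
  fixing an estimator; the simplest standard one is used.

### Protein-level measures

Pairwise combinations (BMA, average, maximum) operate on **direct**
annotation sets; BMA averages each protein's best matches in both
directions. Set-wise measures operate on **ancestor-closed** sets: with
numerator the summed IC of the intersection, SimGIC/SimUIC divide by the
union sum, SimDIC by the arithmetic mean of the two set sums (Dice), and
SimUIX by their maximum; SimUI is the unweighted Jaccard index. Since the
denominators obey union >= max >= mean for a fixed numerator, the scores
obey SimGIC <= SimUIX <= SimDIC. SimUIC shares SimGIC's formula — the
name marks the convention of driving it with the topological rather than
annotation-frequency IC table. Closure is deliberately kept away from the
pairwise family: on proteins annotated with consecutive terms of one
path, closed set overlap converges to 1 regardless of term content (the
Czekanowski-Dice pathology, reproduced in the tests), while BMA under the
topological measure does not. Root terms stay in closures with IC 0: they
never move weighted sums but do enter SimUI's cardinalities, which makes
SimUI reproducible bit-for-bit.

Empty annotation sets (after namespace restriction and evidence
filtering) produce a `None` sentinel rather than 0, and sentinels are
excluded before any ROC/correlation statistic — scoring an unannotated
protein 0 would silently deflate negatives.

## Fixtures and the synthetic generator

Two bundled fixtures carry published expected values. The worked-example
DAG encodes only the topology the source text fixes (root 0 with children
{1,2}; 1 with {3,4}; 2 with three children {4,5,+1}); the otherwise
unconstrained third child of node 2 is a single dummy node, and no
expected value depends on it. The 12-term BP subgraph (DNA-damage
response) uses exactly the 14 published parent-child links; its absolute
positions depend on ~6 levels of unprinted upstream GO, so the published
mantissa/exponent strings and Zhang IC columns are injected verbatim and
the fixture exercises the similarity layer only — the position engine is
instead validated on the worked example and the rational oracle. The
published per-term IC of the subgraph reproduces from the injected
strings to ~1e-6 relative (one value, node 3 of the worked example, is
printed with a fifth-decimal slip; the exact -ln(1/4) is asserted).

`generate_random_dag` grows a single-root DAG node by node: the first
three non-root nodes form a chain (guaranteeing >= 3 levels), later nodes
attach to 1..max_parents earlier nodes with attachment probability
proportional to the square of the node index, which deepens the graph the
way GO grows away from its roots rather than flattening under the root.
Defaults (50 terms, <= 3 parents, 15% part_of, 20 proteins, ~3 direct
annotations per protein drawn with depth-biased probability, evidence
codes 40/30/20/10% EXP/IDA/IEA/ISS) are chosen to look like a small GO
neighbourhood with GOA-style curation. Generated data are exchangeable
DAGs, not GO: they have no namespace structure, no term names, and
annotation depth bias is linear in level rather than curator-driven — so
passing property tests demonstrate correctness of the algorithms, not
biological performance claims.

Property-suite problem sizes — 200 DAGs of <= 40 terms for the oracle
and monotonicity sweeps, 300 DAGs / ~10,200 triples for the metric check —
are the package's own test-design choice: large enough that multi-parent,
multi-path and synonym configurations all occur hundreds of times, small
enough that exact-rational and enumeration oracles stay exact.

## Numerical and design notes

* Tie-break for the minimal-mu ancestor: deeper longest-path level, then
  lexicographic identifier. The score is unaffected; only the reported
  ancestor is.
* Topological order is lexicographic-stable, and products iterate parents
  in sorted order, so every output is deterministic across runs and
  platforms.
* Similarity scores are clipped into [0, 1] to absorb last-ulp rounding.
* Cross-namespace and no-shared-ancestor queries warn and return 0 rather
  than raising, so batch runs over mixed GAF files proceed.
* Duplicate edges are deduplicated with a warning; cycles and unreachable
  terms are hard errors. A term referenced as a parent without its own
  OBO stanza is materialized bare, with a warning, to tolerate truncated
  OBO extracts.
* The evaluation module's threshold default is the Youden-J optimum; it
  is a generic operating point, not a claim about any published table's
  (unstated) threshold choice.

## Limitations

* OWL, cross-namespace links, and term-name search are out of scope.
* The annotation-frequency IC offers no shallow-annotation correction or
  resampling confidence intervals.
* Wang scores on a truncated subgraph differ from whole-ontology Wang
  scores, since S-values propagate to the true root; the bundled subgraph
  fixture therefore carries no recomputable Wang expectations.
* The "resolution" evaluation statistic sometimes reported alongside
  Pearson correlations has no standard closed form and is not
  implemented.
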