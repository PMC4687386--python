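# Methods

## Problem and pipeline

`gamcs` searches for minimal reaction-knockout sets that force a metabolic
network into a desired steady-state behaviour. The pipeline is
EFM enumeration → intervention-problem solving (constrained minimal cut
sets) → genetic-algorithm search over keep/kill partitions of the EFM set.
Each stage is exact; only the outer GA search is heuristic.

## Network representation

A network is the stoichiometric matrix N (m internal metabolites × r
reactions) plus the irreversibility index set. External metabolites are
implicit: exchange reactions simply have one empty side, so no boundary
rows appear in N. Coefficients are stored as exact rationals
(`fractions.Fraction`) with a float view for numerics — elementarity tests
are rank computations that benefit from exactness at desk scale. Up to
three reactions carry design roles (substrate uptake, product secretion,
biomass drain); roles are supplied by configuration, never parsed from
model files. One reaction per role is assumed; summed multi-uptake
normalisation is out of scope for v1.

## EFM enumeration

The enumerator runs the double description method on the pointed cone
{v ≥ 0 : N_split·v = 0} of the reversible-split network: start from the
standard basis rays of the positive orthant, intersect with one metabolite
balance at a time, combine adjacent positive/negative ray pairs
(combinatorial adjacency test on support bitmasks), and sweep out rays
whose support strictly contains another's. Because intermediate cones are
themselves flux cones, support-minimal rays are exactly the extreme rays,
so the sweep is exact. Arithmetic is integer throughout (rows scaled by
denominator LCMs, rays reduced by gcd), so no tolerance enters
enumeration; the `tol_zero = tol_balance = 1e-9` tolerances apply only
when validating externally supplied float vectors against modes normalised
to max |flux| = 1.

Conventions chosen where several are defensible:

- Forward/backward two-cycles of split reversible reactions are removed.
- A mode supported only on reversible reactions is reported once, with
  canonical sign (positive flux at its lowest support index); the reversed
  vector has the identical support and carries no extra information for
  cut-set design.
- Modes are scaled to substrate-uptake flux 1 when the uptake is in the
  support (making yields directly readable), else to max |flux| = 1.
- Output order is lexicographic by support, so mode indices — and hence
  GA individuals and caches — are deterministic across runs.
- An intermediate-ray cap (default 100 000) turns combinatorial blow-up
  into an explicit capacity error; the enumerator targets desk-scale
  models (≲ 80 columns after splitting), not genome scale.

## Constrained minimal cut sets

Minimal hitting sets of the target supports are computed with Berge's
incremental transversal algorithm over bitmask candidates: targets are
deduplicated, superset targets dropped, remaining targets folded in by
ascending size; candidates that miss a target are extended by each of its
elements, and a minimality sweep removes any candidate containing another.
A required cardinality budget (default 8) prunes during folding — the
fitness functions make large cut sets worthless anyway. Constrained MCSs
are obtained by post-filtering MCSs with the survivor constraint
|D^C| ≥ k rather than by a dual formulation; at desk scale the filter is
exact and trivially auditable. Role reactions are forbidden cut members by
default (knocking out the uptake or the product exporter "solves" any
hitting problem while destroying the design); the forbidden set is
configuration.

## Objectives

Per-mode metrics are flux ratios within one EFM: product yield
Y = v_product/v_uptake (times product_carbons/substrate_carbons under
C-mol normalisation, the default — a 6-carbon substrate converted to two
2-carbon product molecules yields 0.6667), biomass yield as a molar ratio
(biomass is not a carbon-countable species), efficiency η = Y·Y_biomass.
Modes without uptake score 0 everywhere.

For a survivor group with minimal observed cut cardinality |C|:

- F1 = w₁·min Y + w₃·(1 − |C|/n)
- F2 = w₂·min η + w₃·(1 − |C|/n)
- F3 = w₁·min Y × w₂·max η + w₃·(1 − |C|/n) + w₄·|D^C|/|E|

min/max range over the surviving modes: min Y is the worst-case guaranteed
yield of the designed strain (rewarding growth-coupled designs), max η its
best growth-coupled survivor. n is the total reaction count of the loaded
network, exchange reactions included, overridable via `n_override` —
published fitness values for comparable small models are sensitive to the
exact n used and cannot always be reconstructed from printed yields and
cardinalities alone, so the package never hard-codes an n to match a
literature value. Ties between patterns break by smaller cut cardinality,
then lexicographically smaller cut set.

## Genetic algorithm

Individuals are binary keep/kill vectors over the n EFMs. Evaluation
builds the coded intervention problem with k = ⌈w_k·|D(S)|⌉ (the ceiling
guarantees k ≥ 1 whenever w_k > 0 and D is non-empty), solves it, groups
cut sets by survivor pattern, scores each pattern at its minimal observed
cardinality, and defines the individual's fitness as its best pattern's
fitness. Infeasible individuals (no cut set within the budget, empty keep
set, or a target hittable only through forbidden reactions) score 0 and
stay selectable only when everything else is 0 — this keeps roulette
selection well defined.

Generation scheme (fixed order): ⌈elit·p⌉ elites carried over unchanged
(so per-generation max fitness is non-decreasing), round(new_S·p)
pattern-based individuals once the archive is non-empty, then mutated
crossover offspring of roulette-selected parents until the population is
full. Stopping: t generations or t_stop consecutive generations without
improvement of the maximum fitness.

Operator details:

- Crossover: textbook 1-point (random split 1 ≤ r_c < n), 2-point,
  uniform (per-position coin at 0.5); offspring conserve the per-position
  parent multiset.
- Mutation flips round(ρ·r_m) distinct positions (round half-up) drawn
  uniformly over all n bits, ρ being the count of modes passing the
  good-mode rule; r_m = 0 disables mutation exactly. Only mutation can
  move a bit outside the good-mode mask.
- Good-mode rule (default `yield>0`) restricts initialisation to modes
  worth keeping; each initial individual keeps between ⌈min_1s·ρ⌉ and ρ
  good modes.
- Pattern-based generation weights each mode by how often it survived in
  all archived patterns (w_t^i), draws a random-sized random subset of the
  nonzero-weight modes, and keeps candidate i iff a uniform draw in
  [0, max w_t) does not exceed w_t^i.
- The archive records each (pattern, fitness) once per *distinct*
  evaluated individual; cache hits return stored results without
  re-recording, so duplicated individuals cannot inflate sampling weights.
- All randomness flows from a single master seed (`GAConfig.seed`);
  results are bit-reproducible. The `threads` key is accepted for
  config-file compatibility, but evaluation is executed serially: an
  individual's evaluation is deterministic and uses no RNG, so any
  parallel schedule would produce identical results.

## Synthetic study system

The default synthetic cell factory is a branched source→sink network: one
substrate uptake feeding S, and eight independent conversion branches —
two maximum-yield producers (2 product/substrate), one half-yield
producer, two growth-coupled mixed branches (product + biomass), one pure
biomass branch and two waste branches. Each branch forces exactly one EFM,
so the 8-mode EFM set, all yields and all optima are known analytically;
the shipped ground-truth table is nevertheless recomputed by an
independent exhaustive subset-scan oracle (for > 20 branches, beyond
oracle scale, the generator warns and derives the table analytically from
the branch definitions instead). The factory emulates the structure of
fermentative strain-design problems — competing fermentative,
respiro-fermentative and overflow routes from one hexose substrate — at a
scale where every keep/kill partition can be scanned. What it does not
emulate: shared internal subpaths between modes (every branch is
support-disjoint apart from uptake/exporters), cofactor and redox
coupling, reversible internal cycles at scale, and the combinatorial EFM
explosion of real networks (10³–10⁶ modes). Passing tests therefore
demonstrate correctness of the machinery and exact optimality at desk
scale, not GA convergence behaviour on genome-scale mode sets.

Study conditions used by the test suite and the acceptance script: GA with
p = 30, t = 50, elit = 0.1, new_S = 0.1, min_1s = 0.9, cut budget 8;
r_m = 0.4 so that round(ρ·r_m) = 2 bits flip per offspring at ρ = 5 —
the same two-to-few-bit regime the operator is designed for at large ρ
(e.g. ρ ≈ 10⁴ with r_m = 2.5·10⁻⁴); w_k = 0.03/0.017/0.04 and
w₂ = 50, w₄ = 1 for F1/F2/F3, following published small-model settings
for the analogous objectives. Five seeds per objective; the optimum
reference is an exhaustive scan over *all* 2^8 partitions (a superset of
scanning partitions of good modes only), so the GA-never-exceeds-oracle
check is airtight.

## Numerical and degenerate-input choices

- Exact integer/rational arithmetic in enumeration; 1e-9 tolerances only
  at float boundaries; fitness comparisons use 1e-12 (strict improvement)
  and 1e-9 (equality against oracle optima).
- Empty target collection → the single empty cut set; empty solution set
  is a valid "infeasible within budget" outcome, distinguished from
  errors; networks admitting no nonzero flux yield an empty EFM set.
- The "don't care" mode status is representable (any support in neither
  collection is simply ignored by the solver), but the GA always
  bipartitions the full EFM set.

## Known limitations

- Enumeration and the exhaustive oracles are desk-scale by design; there
  is no network compression, no genome-scale path.
- One reaction per role; gene–protein–reaction rules, flux bounds and
  compartments are out of scope.
- The GA inherits the usual heuristic caveats (local optima on large
  instances); multiple seeds are the intended mitigation.
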