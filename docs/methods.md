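# Methods

## Problem and definitions

The input is an undirected simple graph *G* (vertices: proteins or genes;
edges: functional association above a confidence cutoff) and a query set
*Q* of vertices representing prior knowledge, e.g. proteins already linked
to a phenotype.  For thresholds γ ∈ (0.5, 1] and μ ∈ (0, 1]:

* *S ⊆ V(G)* is **γ-dense** iff every *v ∈ S* has at least
  ⌈γ(|S|−1)⌉ neighbours inside *S*.  The per-vertex form (rather than a
  global edge fraction) forces uniform density: no member may free-ride on
  the others' connectivity.
* *S* is **μ-enriched** iff |S ∩ Q| ≥ μ|S|.
* The output is every **maximal** set that is both, with |S| ≥ `min_size`:
  no strict superset is again dense and enriched.  Maximality is global —
  *not* "no single vertex can be added" — because feasibility is not
  anti-monotone (see below).

Since μ > 0 implies ⌈μ|S|⌉ ≥ 1, every feasible module contains at least
one query vertex; seeding the search only from query vertices is therefore
complete.  Because γ > 0.5, any two members of a dense set share a
neighbour inside it, so every module has diameter ≤ 2 in *G*; this is the
basis of the candidate restriction below.

## Search

For each seed *v₀ ∈ Q* in ascending vertex order, the search grows a
subgraph *S* (initially {v₀}) from a candidate set *C* (initially the
distance-≤2 neighbourhood of *v₀*).  Children add one candidate at a time
in ascending index order, keeping only higher-indexed candidates within
distance ≤ 2 of the new member, so each vertex set is visited along exactly
one path.  Earlier seeds are excluded from later searches: a module is
discovered from its smallest-index query member.  `s_a(v)` and `c_a(v)`
denote the number of neighbours of *v* in *S* and *C*.

At every node, in order:

1. **Candidate prunes (fixed point).**  Degree feasibility: drop *v ∈ C*
   unless `s_a(v) + c_a(v) ≥ ⌈γ(|S| + c_a(v))⌉` — the degree *v* would need
   if it joined together with all of its candidate neighbours (the best
   case for *v*, since adding a non-neighbour raises the bar without
   raising its degree).  Enrichment feasibility: the branch dies unless
   `|S∩Q| + |C∩Q| ≥ μ(|S| + |C∩Q|)` (the enrichment of the best extension,
   which absorbs every query candidate); while the branch lives, a
   non-query candidate is dropped if admitting it would violate that bound
   permanently.  Removals lower other candidates' `c_a`, so both rules
   iterate to a fixed point.
2. **Registry backtrack.**  If an already-discovered module contains all of
   *S ∪ C*, nothing in this subtree can be maximal (the covering module is
   feasible, so any subset found here would be dominated) — backtrack.
3. **Emission.**  If *S* is dense, enriched and large enough, and no single
   vertex *w* anywhere in *G* yields a feasible *S ∪ {w}* (a cheap
   necessary condition for maximality), register *S* in the bitmap index
   and record it as a candidate module.
4. **Expansion bound.**  If some member has
   `s_a(v) + c_a(v) < ⌈γ(|S| + c_a(v) − 1)⌉`, no supergraph within *S ∪ C*
   can be dense; stop expanding.
5. Otherwise recurse on each remaining candidate.

**Non-anti-monotonicity and the final filter.**  A superset of an
infeasible set can be feasible (wheel graphs give small witnesses), so no
local stopping rule can certify maximality.  After all seeds finish, a
global subset filter keeps exactly the recorded sets that are strict
subsets of no other recorded set.  Correctness rests on this filter plus
completeness of the traversal; the registry backtrack and the emission
check are optimisations.  Soundness of every prune is argued from the
"best-case extension" inequalities above (each rule only ever discards
vertices/branches that provably cannot participate in a feasible set inside
the current subtree, while any maximal module survives on its canonical
path), and is additionally verified empirically by exact agreement with
exhaustive subset enumeration over 200 random graphs × 9 parameter
settings, with each prune disabled individually and jointly.

One printed form of the candidate bound ("|N²(S)|/|S| entries") divides by
|S|; we implement the underlying distance-2 restriction and do not rely on
that expression.  The expansion bound is implemented with "≥ against the
ceiling" — the weaker, sound reading of the printed strict inequality —
and the emission on expansion-bound failure re-checks S's own feasibility
rather than trusting the bound alone.

## Exact threshold arithmetic

γ and μ are stored as rationals (floats are converted through their
shortest decimal representation, so 0.75 means 3/4).  Every comparison is
cross-multiplied integer arithmetic; ⌈γ(s−1)⌉ is an integer ceiling
division.  This matters at boundaries: γ = 0.999 demands full adjacency
for every module below 1001 vertices (the "clique" regime), and
γ = 1/2 + 10⁻⁹ is the smallest practical density strictly inside the
admissible interval, used where a benchmark regime nominally sits at the
excluded value 0.5 exactly.

## Bitmap registries

Discovered modules get sequential ids.  Each vertex carries a bitset (bit
*i* ⇔ module *i* contains it); "is some discovered module a superset of
*X*?" is the AND of the members' bitsets.  The **flat** index ANDs full
bitsets.  The **hierarchical** index keeps summary layers — one bit per
byte of the layer below (1 = byte nonzero), a new layer appended whenever
the top layer outgrows one byte — and descends only into bytes whose
summary AND is nonzero.  Both backends are exchangeable and are tested to
answer identically on random workloads (10⁴ registrations, 10³ queries)
and to leave enumeration output unchanged.  Bitsets are arbitrary-precision
ints; vertices in no module carry no storage.

## Synthetic data

**R-MAT.**  Benchmark graphs are recursive-matrix graphs: each edge picks
one quadrant of the adjacency matrix per bit level with probabilities
(a, b, c, d) = (0.45, 0.15, 0.15, 0.25), giving the heavy-tailed,
power-law-like degree structure of real association networks (maximum
degree > 3× the mean at scale 10 on every seed tried).  Defaults follow
the benchmark design the package is validated against: 2^scale vertices,
edge_factor = 7 so the mean degree is 14 before cleanup.  The directed
quadrant draw is symmetrised by sorting endpoints; self-loops and duplicate
draws are rejected and redrawn so the edge count is exact; isolated
vertices are removed afterwards.  All randomness flows from one integer
seed.  What this does *not* emulate: real networks' edge-confidence
structure, assortativity, and annotation bias in Q — passing benchmarks
says the algorithm scales on skewed sparse graphs, not that modules found
in a real organism are biologically meaningful.

The published benchmark table reports |E| exactly 7×|V| *after* isolated
vertex removal for every graph, which no natural generate-then-clean order
produces; its counts are therefore treated as stochastic targets (means
over ≥25 seeds), and the near-clique regime is additionally verified
exactly against an independent maximal-clique enumerator on the same
graphs.

**Planted modules.**  For recovery tests, a set of `size` random vertices
is wired up (most-deficient-first, deterministic per seed) until every
member meets ⌈γ(size−1)⌉ internal neighbours, and ⌈query_fraction·size⌉ of
them are marked as query vertices.  Over 50 trials (200-vertex sparse
background, size 8, γ = 0.75, half the members as queries, μ = 0.5) the
planted set is contained in a returned module in 50/50 trials — guaranteed
by exactness, so this test guards the pipeline, not a recovery rate.

## Benchmark regimes

| regime   | γ          | μ     | Q                |
|----------|------------|-------|------------------|
| clique   | 0.999      | 0.001 | every vertex     |
| enriched | 0.5 + 10⁻⁹ | 0.90  | every 10th vertex|
| dense    | 0.85       | 0.85  | every 6th vertex |

Query strides are taken over internal indices after isolated-vertex
removal.  Timing is reported per module and is hardware-dependent; the only
asserted timing property is ordinal (the clique regime is cheapest per
module).  The suite runs the published-count comparison at scale 10 and the
index-equivalence benchmark at scale 10, and `scripts/acceptance.py` runs
scales 10–12 with 25 seeds per target; these sizes keep a full validation
run in minutes on one CPU while already exercising graphs 300× larger than
the oracle-checked ones.

## Parameter guidance and defaults

* `gamma` (default 0.75): 1.0 finds only cliques; real networks miss
  edges, so the midpoint of the admissible density range is the usual
  working value for functional modules.
* `mu` (default 0.001): with any module below 1001 vertices this means "at
  least one query member" — the broadest guilt-by-association sweep.
  μ ≥ 0.5 returns modules dominated by prior knowledge.
* `min_size` (default 2): singletons are vacuously dense and would flood
  the output.
* `--score-threshold` (default 700): the conventional high-confidence
  STRING cutoff; the right value is organism- and evidence-dependent and
  must be a deliberate choice.
* Index backend (default hierarchical): results never depend on it; flat
  can be faster when few modules are found.

## Known limitations

* Worst-case time is exponential — inherent to complete quasi-clique
  enumeration; the prunes make sparse, skewed graphs practical.
* Density is purely topological; edge weights only enter through the
  read-time threshold.
* The enriched regime (γ barely above ½, high μ) is the slowest per module
  and the most sensitive to how the admissible-density boundary is read;
  with the ceiling semantics used here its module counts on R-MAT graphs
  sit well below the published table's figures, and no parameter choice
  consistent with the definitions reproduces them (see the repository's
  validation suite for the measured bands).
* The oracle is limited to 22 vertices; beyond that, correctness evidence
  is indirect (prune/index invariance, the clique-limit cross-check, and
  monotonicity properties).
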