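# Methods

## Problem formulation

A molecule is a graph of atoms (element, valence-electron count ν) and
bonds, plus a total charge q_T. Every bond is granted a baseline electron
pair; the remaining budget e_T = -q_T - 2·N_B + Σν is distributed over
atoms and bonds subject to per-position capacities derived from target
valencies τ (H: 2; P/S with degree ≥ 3: 10/12; otherwise 8 — the
hypervalency rule is applied purely on degree, so e.g. PH₃ gets τ = 10).
Atoms whose sigma framework alone exceeds τ, molecules with odd e_T
(radicals) and molecules whose capacity cannot hold e_T are rejected. All
capacities are even, so the default **pair mode** — placing electron pairs
instead of single electrons — is lossless and halves the search depth; it
is used throughout and by every test.

An assignment's score sums per-member table lookups; an atom's key encodes
(element, formal charge), a bond's key (element pair, total electron
count). Missing keys score +∞, as does any atom whose valence (own
electrons + baseline-inclusive bond electrons) exceeds τ. Two algebraic
identities hold for every *complete* assignment and are enforced as tests:
Σ F(v) = q_T and total electrons = e_T + 2·N_B.

## The packaged score table

The shipped table (`lewisopt/data/default_scores.tab`) is a **synthetic
surrogate**, not a quantum-chemistry dataset: atom scores approximate
literature (cumulative) ionization energies and electron affinities in eV
(so e.g. O⁻ is slightly favourable at −1.46, O⁺ costs 13.6, multiply
charged states escalate steeply), and bond scores are
BDE(highest order for the pair) − BDE(this order), making higher bond
orders cheaper, balanced against the charge-separation costs. Pairs with
no tabulated multiple-bond data carry only a single-bond entry. This
ordering reproduces textbook Lewis structures for the fixture molecules
(carbonyls, carboxylates, kekulé benzene, hypervalent sulfate) but it is
*not* claimed to reach any particular accuracy on real databases; tests
passing with it demonstrate correctness of the optimisation machinery, not
chemical accuracy of the scores. Users can drop in their own table via the
documented `ATOM`/`BOND` text format.

Two numerical choices matter:

* All table values are quantized to multiples of 1/256 eV. Sums of dyadic
  rationals of this magnitude are exact in double precision, so the three
  optimizers produce *bitwise identical* optimal scores regardless of
  summation order, and score comparisons can use exact equality — there is
  no tolerance anywhere in the scoring path.
* `swap_c0_cminus` (default on) exchanges the C⁰ and C⁻ atom scores at
  load time, making neutral carbon strictly preferable to carbanions.

## Optimizers

**Local.** Greedy setup (place one pair at a time wherever the total score
is lowest), then steepest descent over all source→target single-pair
moves. Ties break deterministically by position order (vertices by index,
then edges lexicographically). On all-infinite plateaus, unvisited sideways
moves are taken so descent can find finite territory, mirroring the
observation that some initial assignments need many steps before a finite
score appears. A wall-clock timeout (default 5 s) returns best-so-far with
a `timed_out` flag. `follow_ties` optionally expands every equal-lowest
neighbour breadth-wise.

**A\*.** Levels of the search tree decide the electron count of one
position each, ordered by a BFS that keeps each atom adjacent to its
incident bonds so members become *calculable* early. A member is calculable
once its score is fully determined: for an atom, its own count and all its
incident bond counts are decided (or were never positions); for a bond,
both endpoints are calculable. g sums calculable-member scores; h adds, for
every other member, the minimum score over the electron counts (bonds,
valence-feasible) or formal charges (atoms, reachable within remaining
valence room) it can still attain — a superset of the truly reachable
options, hence admissible; the first completed node popped is optimal.
Children with f above the local-optimisation score + 1 are pruned. Memory
is accounted as queue length × a documented per-node constant
(96 + 8·|P| bytes) against the configured cap (default 1024 MB); exceeding
it raises without a partial answer. One shortcut: if the queue's minimum f
is +∞, admissibility implies every completion is +∞, so the search reports
an infinite score immediately instead of enumerating the whole tree.

**FPT.** A tree decomposition is built with the greedy minimum-fill-in
elimination heuristic (ties: fewest fill edges, then smallest degree, then
smallest index) and refined into a *nice* decomposition (leaf / introduce /
forget / join nodes, empty root and leaves, bags changing by one member).
Because bonds must be scored too, they are promoted to bag members: a bond
belongs to every bag containing at least one endpoint. This membership rule
has two properties we rely on (both re-checked by validation tests on 200
random graphs): the bags containing any member form a connected subtree,
and when an atom is forgotten all its incident bonds are still in the bag —
so its formal charge and valence are computable there — while each bond is
forgotten (and scored) immediately after its second endpoint. Each node
carries a sparse table S_t[l, k]: the minimum score of the members already
forgotten below t, given l units forgotten and bag counts k; infeasible
budgets are pruned with the window
max(0, e_T − (|𝒫| − cap(forgotten))) ≤ l ≤ min(e_T, cap(forgotten)).
Introduce nodes add an unconstrained coordinate, forget nodes minimise over
the forgotten member's count (adding its score in the context of the bag),
join nodes convolve the children's budgets over a shared k. The root bag is
empty, so the answer is S_root[e_T, ()] — the final forget chain plays the
role of the root-node recurrence.

**Resonance enumeration.** With all node tables retained, every arg-min
choice is backtracked depth-first (counts ascending, children before
parents), yielding each minimum-score assignment exactly once, deduplicated
defensively, deterministic in order, and capped (default 32) with a
`truncated` flag, since disjoint resonance substructures multiply.

**Pre-placement** (off by default, matching the consistency-test protocol)
fixes three lone pairs on terminal halogens and two on terminal octet O/S,
then solves the reduced problem; equivalence of the reduced optimum is
verified against exhaustive enumeration in the tests.

## Synthetic molecule generator

`generate_synthetic` emulates the *shape* of small organic molecules:
random connected heavy-atom trees (4–10 heavy atoms; C-rich element
distribution with N, O, S, P and halogens) with occasional ring closures,
degrees capped at conventional connectivities (C 4, N 3, O 2, S/P 3 — so
hypervalent τ arises for 3-coordinate S/P), hydrogens filled to capacity
minus an occasional unsaturation of 1–2, and charge in {−1, 0, +1} chosen
to keep the electron count even. Every output passes the dataset filters by
construction. What it does **not** emulate: realistic functional-group
statistics, aromatic ring frequency, large conjugated systems, or the size
distribution of real databases — so passing tests demonstrate algorithmic
correctness (optimality, conservation, decomposition validity) on graphs
of realistic topology, not accuracy on real chemical data. Oracle suites
additionally cap the total multiset capacity at 12 pairs so exhaustive
enumeration stays cheap; the consistency suite uses 200 molecules and the
oracle suite 500, sizes chosen to keep the whole suite around ten seconds
on one core while still exercising joins, rings and hypervalent centres.

## Dataset filtering and I/O

The screening rules run in a fixed order: dangling bonds (dummy/attachment
atoms), ≤ 3 heavy atoms, unsupported elements, odd valence-electron count,
duplicates. Duplicate detection treats molecules as element-labelled
connectivity graphs (orders and charges stripped), hashed by
Weisfeiler–Lehman and confirmed by isomorphism — a deliberate, checkable
definition of "identical". File parsing (SDF/MOL, MOL2, SMILES with
hydrogen expansion, PDB+CONECT) delegates to RDKit; input bond orders and
formal charges are kept only as reference data for validation and never
reach the optimizer. Disconnected records are split into one problem per
component with per-component charges from the record's atom charges.

## Known limitations

* Open-shell species (odd e_T) are rejected, not modelled.
* Aromatic output is kekulized only; no fractional orders.
* The surrogate table's absolute energies are approximate; only the
  orderings that drive the fixtures were designed for.
* GreedyFillIn is a width upper bound, not exact treewidth; pathological
  graphs could inflate DP cost (molecular graphs in practice have width
  1–3).
* The A* memory estimate is an accounting model, not an OS measurement;
  it exists to give a portable, reproducible trigger.
* SMILES hydrogen expansion uses standard implicit-valence rules; inputs
  typed under other conventions may gain different hydrogen counts.
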