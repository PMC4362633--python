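# Methods

## The representation

A knowledge base has four parts: a class taxonomy (multiple parents
allowed, acyclic) with pairwise disjointness declarations; a relation
hierarchy (each relation optionally under one parent, optionally paired
with an inverse, and tagged with a kind: participant, structural, spatial,
functional, property or taxonomy-internal); *graph rules*; and standalone
cardinality constraints `(class, relation, filler class) → min..max`.

A graph rule describes every instance of its root class by a connected
directed graph of typed variables: the single universally quantified root
and any number of existential nodes, with edges `relation(subject, object)`
and literal-valued property assertions on nodes. Nothing restricts the
graph to a tree — a node may have several incoming edges, and edges may
point back into the root.

Rules are stored **Skolemized**. Each existential node is replaced by a
function term over the root variable, named `<node-class>-of` (kebab-cased,
with an ordinal suffix on collision inside one rule: `ribosome-of`,
`ribosome-of-2`). Function symbols are fresh per rule, so term identity is
`(rule, function, argument)`; the textual form `ribosome-of@cell-parts(x)`
carries the scope. Skolemization is pure and deterministic, and
de-Skolemizing reproduces a rule isomorphic to the original.

**Equality statements** link a rule's term to a term of another rule in the
same subclass lineage (`eukaryotic-chromosome-of(x) = chromosome-of(x)`).
This is how a subclass specializes an inherited filler. Equalities between
rules of taxonomically unrelated classes are rejected: outside a shared
lineage the two rules never ground on the same root individual, so such a
statement could never fire and is almost certainly an authoring error.
Multiple rules per class are allowed and read conjunctively.

Negative information has no dedicated connective; it is encoded the way
the representation already allows: class disjointness (a polar molecule is
not a nonpolar molecule), `exactly 0` cardinality constraints (a protoplast
has no cell wall), relations with negative meaning, or negative property
values (`solubility-in-water = insoluble`).

## The tree-model check

For each rule we form the directed graph over its variables with one edge
per binary predicate (first argument → second argument) and report every
node with ≥ 2 distinct incoming edges — distinct meaning distinct
(subject, relation) pairs, so parallel edges through different relations
count separately — plus the root if it has any incoming edge at all (a
rooted description whose root is entered from inside the graph is not a
tree either; this also covers directed cycles in which every node has
exactly one predecessor). With this definition, for every connected rule:

    offending nodes exist  ⇔  |edges| > |nodes| − 1
                           ⇔  the OWL2 export drops at least one edge,

and the number of dropped edges is exactly |edges| − (|nodes| − 1). The
test suite checks this equivalence on all fixtures and on hundreds of
random rules.

## Elaboration

`elaborate(kb, class, depth)` creates a seed individual and applies every
rule of the class and its superclasses, grounding each Skolem term on the
root individual (ground ids are the applied terms, e.g.
`chromosome-of@cell-parts(c1)`, which makes re-application idempotent).
Declared equalities are merged with union-find *before* the filler
individuals are recursed into, so later rule applications see the merged
labels; a merge whose united labels contain two disjoint classes raises a
consistency error. Recursion into fillers is bounded by `depth` = number of
rule-application levels below the seed (default 3 — two levels beyond the
direct description, enough for every bundled example while keeping
elaboration of cyclic part structures, like the plant cell whose wall is
part of the cell that synthesizes it, small). After the fixpoint, inverse
relations are closed (if `has-part(a,b)` and an inverse is declared,
`is-part-of(b,a)` is added).

Termination needs no extra guard: ground-term identity deduplicates
re-application, and the depth bound stops recursive classes. An earlier
design sketch called for refusing to re-apply a (rule, class) pair found in
an individual's origin chain; that guard would wrongly truncate legitimate
recursive descriptions (a class whose filler is the same class) above the
depth bound and would break monotonicity in depth, so it was dropped.

Elaboration is deterministic (all iteration is over sorted keys) and
monotone in depth: the triples at depth d are a subset of those at d+1.

**Cardinality-driven equality inference** is separate and explicit
(`infer_cardinality_equalities`): for every `exactly 1` constraint and
every individual with ≥ 2 fillers of the constrained class, the fillers are
merged when their most-specific labels are pairwise subsumption-comparable.
Incomparable fillers are left alone — they are not *provably* identical;
disjoint fillers under an `exactly 1` bound are a genuine contradiction and
raise. The operation is idempotent. It is not folded into `elaborate`
because attaching such constraints is often wrong (a eukaryotic cell does
not have exactly one chromosome), so the caller must opt in.

## Query evaluation

* **Relation values** (Q1): answers are read off the seed's outgoing
  triples of the elaborated graph; each answer is the most specific label
  of the filler after merging. With `expand`, the transitive sub-relation
  closure is queried and each answer is tagged with the relation it
  actually came through (structure queries fan out over has-part,
  has-region, material, possesses; `spatial_relations_among` then adds the
  spatial triples among those fillers, completing a structural
  description). The during-variant elaborates both the entity and the
  event into one graph and keeps only events that are the target event or
  its subevent-closure steps.
* **Taxonomy** (Q2): transitive closure over the class graph; the subclass
  test is reflexive.
* **Cardinality** (Q3): breadth-first up the superclass chain; at each
  level both standalone constraints and cardinality-annotated rule edges
  (matched by the subject node's class) are consulted; the first level with
  a hit wins, so a subclass constraint overrides a superclass one.
* **Describe** (Q4): exactly the union of Q1 over all relations present,
  Q2, and Q3 for every (relation, filler) pair plus declared constraints —
  nothing else.
* **Compare** (Q5): slots aligned by relation name; within a slot, filler
  pairs are aligned greedily — exact class matches first, then by deepest
  common ancestor (depth = longest superclass chain; ties broken on the
  sorted pair, which makes the result symmetric under swapping the
  arguments). Aligned equal fillers are similarities; aligned distinct
  fillers are reported as differences (the eukaryotic chromosome against
  the plain chromosome); unmatched fillers and slots present on one side
  only are differences too. Output is structured data; no prose is
  generated.
* **Relationship paths** (Q6): taxonomic chains are searched first and
  reported over `subclass-of`/`superclass-of` pseudo-relations; then all
  simple triple-paths of the elaborated graph from the seed to the *first*
  encountered instance of the target class, up to `max_depth` hops.
  Ranking must be total for determinism: path length, then the tuple of
  relation priorities (taxonomy 0, structural 1, spatial 2, participant 3,
  everything else 4), then the relation names lexicographically. The
  analogy question replays each X→Y relation signature from a sample of A;
  the importance question starts at a property of X (a possessed quality
  or a property-relation filler), ends at a has-function filler, and keeps
  only paths containing a `facilitates` edge.

## File formats

The native dialect is line-oriented (blocks `class` / `relation` /
`constraint` / `rule … end`, `;` comments, identifiers
`[A-Za-z0-9][A-Za-z0-9-]*`); the full grammar is in the
`biokr.io_formats` module docstring. Serialization is canonical (sorted
declarations), and `parse(serialize(kb))` equals `kb` structurally.
Equalities are attached only after all rules of a document are installed,
so they may reference rules declared later in the file.

The OWL2 functional export turns each rule into a subclass axiom nesting
existential restrictions along a breadth-first spanning tree of the rule
graph (undirected traversal, lexicographic tie-breaks; an edge used
against its direction is wrapped in `ObjectInverseOf`). Cross edges and
equality statements are inexpressible in that shape: they are dropped and
itemized in a `LossReport`; equalities are additionally emitted as
`rdfs:comment` annotations so no semantics are silently invented.
Cardinalities become qualified number restrictions. The export is checked
structurally (balanced, declared, deterministic) in the tests; it has not
been run through an external OWL toolchain.

The first-order export is TPTP-style text, one `fof` per axiom, with
Skolem terms and equalities preserved verbatim and relation metadata and
cardinality bounds reified into dedicated predicates so nothing is lost.
`parse_fol` reads exactly this fragment back; round-tripping reproduces
the knowledge base up to rule-variable renaming (existential variables are
renamed to their Skolem function names).

## Synthetic data and oracles

The generator (`SynthParams`) draws valid KBs: a random taxonomy (each
class at most one random earlier parent, p = 0.7), a small relation
hierarchy with mixed kinds, and per class 0..`rules_per_class` rules built
as a root-directed random spanning tree of 1..`max_nodes_per_rule` nodes
plus, with probability `cross_edge_prob`, one extra (non-duplicate) edge —
which provably breaks the tree property — plus occasional property
assertions, edge cardinalities, equalities into ancestor rules (only
between subsumption-comparable node classes) and standalone constraints.
Defaults (8 classes, 4 relations, ≤ 4 nodes per rule, cross-edge and
equality probability 0.4 in the agreement suites) keep each KB small
enough for the brute-force oracle while exercising every feature;
generation is fully determined by the seed. No disjointness is generated,
so random equality merges cannot be inconsistent by construction.

The oracles are deliberately naive and share no code path with the
reasoner: the materializer mints fresh individuals on every rule
application and then merges exhaustively — by ground-term identity and by
declared equalities — until fixpoint, re-entering the apply loop when a
merge reveals new labels; the path enumerator is a plain recursive DFS.
Comparisons are on answer sets (for paths, on id-independent fingerprints
of label sets and relations), never on ranking, which is a reasoner-side
convention the oracles ignore.

What the synthetic KBs do not emulate: real textbook scale (hundreds of
thousands of axioms), deep relation hierarchies, or semantically
meaningful class names. Passing the agreement suites shows the two
implementations compute the same theory on small inputs; it says nothing
about elaboration cost or modeling quality on a full curriculum-scale KB.

## Known limitations

* Skolemized rules are logically *stronger* than the existential
  originals; that approximation is inherited by everything downstream.
* `check_consistency` flags only exceeded `exactly` bounds; under-filled
  bounds are not violations under an open-world reading of an elaboration.
* An equality whose two sides ground to individuals of disjoint classes is
  an error at elaboration time, not at authoring time (it depends on which
  rules fire together).
* Necessary-and-sufficient condition classification, full theorem proving,
  English question understanding and prose generation for comparisons are
  out of scope.
* The OWL2 output follows the functional-syntax grammar but has only been
  validated structurally, not by an external reasoner.
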