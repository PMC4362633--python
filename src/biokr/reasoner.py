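"""Question answering over elaborated sample-instance graphs.

Every query about a class is answered the same way the underlying
representation intends: create a *sample instance* of the class, apply every
Skolemized rule of the class and its superclasses (grounding each Skolem
term on the sample individual), merge individuals linked by equality
statements, and read the answer off the resulting instance graph. The six
operation families supported are

* relation-value queries, optionally expanded over the sub-relation
  hierarchy (``what are the parts / the structure of X?``), including the
  during-variant constrained to sub-steps of an event;
* taxonomic queries (transitive sub/superclass closure);
* cardinality-constraint lookup;
* concept description (exactly the union of the previous three);
* description comparison (similarities and aligned differences);
* relationship-path search between two classes, with the derived analogy
  (``X is to Y as A is to what?``) and property-importance (paths through
  ``facilitates``) questions.

Search and ranking are deterministic: paths are ordered by length, then by
relation priority (taxonomy before structural before spatial before
participant before anything else), then lexicographically.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Literal, Optional, Union

import networkx as nx

from .kb_core import (
    CardinalityConstraint,
    ConsistencyError,
    Individual,
    InstanceGraph,
    KBError,
    KnowledgeBase,
    RelationKind,
    SkolemTerm,
)

__all__ = [
    "Description",
    "ComparisonResult",
    "Path",
    "elaborate",
    "infer_cardinality_equalities",
    "query_relation_values",
    "query_during",
    "taxonomy_query",
    "cardinality_query",
    "describe",
    "compare",
    "find_relationship",
    "analogy",
    "trace_importance",
    "SUBCLASS_OF",
    "SUPERCLASS_OF",
]

DEFAULT_DEPTH = 3

#: Pseudo-relations used for taxonomy links in relationship paths.
SUBCLASS_OF = "subclass-of"
SUPERCLASS_OF = "superclass-of"

_KIND_PRIORITY = {
    RelationKind.TAXONOMY_INTERNAL: 0,
    RelationKind.STRUCTURAL: 1,
    RelationKind.SPATIAL: 2,
    RelationKind.PARTICIPANT: 3,
    RelationKind.FUNCTIONAL: 4,
    RelationKind.PROPERTY: 4,
}


# ---------------------------------------------------------------------------
# Result types


@dataclass(frozen=True)
class Description:
    """Everything known about a class: taxonomy, relation values,
    cardinality constraints (the three sub-queries, nothing more)."""

    cls: str
    superclasses: frozenset[str]
    subclasses: frozenset[str]
    relation_values: tuple[tuple[str, frozenset[str]], ...]  # relation -> filler classes
    cardinalities: tuple[tuple[tuple[str, str], CardinalityConstraint], ...]

    @property
    def relation_value_map(self) -> dict[str, frozenset[str]]:
        return dict(self.relation_values)

    @property
    def cardinality_map(self) -> dict[tuple[str, str], CardinalityConstraint]:
        return dict(self.cardinalities)


@dataclass(frozen=True)
class ComparisonResult:
    """Aligned similarities and differences of two concept descriptions."""

    x: str
    y: str
    similarities: tuple[tuple[str, str], ...]  # (relation, shared filler ancestor)
    differences: tuple[tuple[str, Optional[str], Optional[str]], ...]
    slots_only_in_x: tuple[str, ...]
    slots_only_in_y: tuple[str, ...]

    @property
    def is_identical(self) -> bool:
        return not self.differences and not self.slots_only_in_x and not self.slots_only_in_y


@dataclass(frozen=True)
class Path:
    """An ordered chain of instance-graph triples with its relation signature."""

    triples: tuple[tuple[str, str, str], ...]

    @property
    def relations(self) -> tuple[str, ...]:
        return tuple(r for _, r, _ in self.triples)

    def __len__(self) -> int:
        return len(self.triples)

    def __str__(self) -> str:
        if not self.triples:
            return "(empty path)"
        out = [self.triples[0][0]]
        for _, r, o in self.triples:
            out.append(f"--{r}--> {o}")
        return " ".join(out)


# ---------------------------------------------------------------------------
# Elaboration


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}
        self.birth: dict[str, int] = {}
        self._n = 0

    def add(self, x: str) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.birth[x] = self._n
            self._n += 1

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> str:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        keep, drop = (ra, rb) if self.birth[ra] <= self.birth[rb] else (rb, ra)
        self.parent[drop] = keep
        return keep


def _seed_id(cls: str, taken: set[str]) -> str:
    initials = "".join(part[0].lower() for part in cls.split("-"))
    n = 1
    while f"{initials}{n}" in taken:
        n += 1
    return f"{initials}{n}"


def _ground_id(term: SkolemTerm, root_id: str) -> str:
    return f"{term.function_name}@{term.scope}({root_id})"


def elaborate(
    kb: KnowledgeBase,
    cls: str,
    depth: int = DEFAULT_DEPTH,
    *,
    graph: Optional[InstanceGraph] = None,
) -> InstanceGraph:
    """Build the sample-instance graph for ``cls``.

    A seed individual of ``cls`` is created; every rule of the class and its
    superclasses is applied, each existential node grounding its Skolem term
    on the root individual; Skolem terms linked by declared equalities are
    merged into one individual whose labels are the union of both terms'
    classes (an error if those are disjoint). Rules then recurse into the
    filler individuals, ``depth`` bounding the number of rule-application
    levels below the seed. The output is deterministic and monotone in
    ``depth``, and the inverse closure over declared inverse relations holds.

    ``graph`` lets callers elaborate several classes into one shared graph
    (used by the during-query).
    """
    if cls not in kb.classes:
        raise KBError(f"unknown class {cls!r}")
    if depth < 1:
        raise KBError(f"depth must be >= 1, got {depth}")
    g = graph if graph is not None else InstanceGraph()
    uf = _UnionFind()
    for known in g.individuals:
        uf.add(known)

    seed = _seed_id(cls, set(g.individuals))
    g.individuals[seed] = Individual(seed, "seed", {cls})
    uf.add(seed)

    def get_or_create(gid: str, label: str, origin: Union[SkolemTerm, str]) -> str:
        rep = uf.find(gid) if gid in uf.parent else None
        if rep is None:
            g.individuals[gid] = Individual(gid, origin, {label})
            uf.add(gid)
            return gid
        g.individuals[rep].class_labels.add(label)
        return rep

    def merge(a: str, b: str) -> str:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            return ra
        labels = g.individuals[ra].class_labels | g.individuals[rb].class_labels
        for la in labels:
            for lb in labels:
                if la < lb and kb.disjoint(la, lb):
                    raise ConsistencyError(
                        f"equality merge of {ra!r} and {rb!r} joins disjoint classes {la!r}/{lb!r}"
                    )
        keep = uf.union(ra, rb)
        drop = rb if keep == ra else ra
        g.individuals[keep].class_labels |= g.individuals[drop].class_labels
        del g.individuals[drop]
        return keep

    applied: set[tuple[str, str]] = set()
    raw_triples: list[tuple[str, str, str, str]] = []  # (s, r, o, provenance)
    raw_props: list[tuple[str, str, str]] = []
    queue: deque[tuple[str, int]] = deque([(seed, depth)])

    while queue:
        iid, budget = queue.popleft()
        iid = uf.find(iid)
        if budget < 1:
            continue
        ind = g.individuals[iid]
        lineage: set[str] = set()
        for lbl in ind.class_labels:
            lineage |= kb.superclasses(lbl, reflexive=True)
        children: list[str] = []
        pending_eqs: list[tuple[str, str]] = []
        for c in sorted(lineage):
            for rule in sorted(kb.rules.get(c, []), key=lambda r: r.rule_id):
                if (iid, rule.rule_id) in applied:
                    continue
                applied.add((iid, rule.rule_id))
                ground: dict[str, str] = {rule.root_var: iid}
                for var, term in rule.terms:
                    gid = _ground_id(term, iid)
                    node = rule.node(var)
                    ground[var] = get_or_create(gid, node.class_label, term)
                    children.append(gid)
                for e in rule.edges:
                    raw_triples.append((ground[e.subject], e.relation, ground[e.object], rule.rule_id))
                for var, prop, lit in rule.property_assertions:
                    raw_props.append((ground[var], prop, lit))
                for eq in rule.equalities:
                    pending_eqs.append((_ground_term(kb, eq.left, iid), _ground_term(kb, eq.right, iid)))
        for lid, rid in pending_eqs:
            la = _ensure_term_individual(kb, g, uf, get_or_create, lid)
            rb = _ensure_term_individual(kb, g, uf, get_or_create, rid)
            merge(la, rb)
        for gid in children:
            queue.append((gid, budget - 1))

    for s, r, o, prov in raw_triples:
        g.add_triple(uf.find(s), r, uf.find(o), prov)
    for s, p, lit in raw_props:
        g.property_values.add((uf.find(s), p, lit))
    g.close_inverses(kb)
    return g


def _ground_term(kb: KnowledgeBase, term: SkolemTerm, root_id: str) -> str:
    return _ground_id(term, root_id)


def _ensure_term_individual(kb, g, uf, get_or_create, gid: str) -> str:
    """Resolve a ground Skolem term to its (possibly pre-existing) individual.

    An equality may name a term of a rule applied in the same round; if the
    term was not grounded yet (the other rule contributed nothing else), the
    individual is created with the defining node's class label.
    """
    if gid in uf.parent:
        return uf.find(gid)
    fn_scope, _, _ = gid.partition("(")
    fn, _, scope = fn_scope.partition("@")
    rule = kb.rule_by_id(scope)
    if rule is None:
        raise KBError(f"equality references unknown rule {scope!r}")
    var = next(v for v, t in rule.terms if t.function_name == fn)
    return get_or_create(gid, rule.node(var).class_label, rule.term_map[var])


# ---------------------------------------------------------------------------
# Cardinality-driven equality inference


def infer_cardinality_equalities(kb: KnowledgeBase, graph: InstanceGraph) -> InstanceGraph:
    """Merge fillers forced equal by an ``exactly 1`` constraint.

    For each individual, relation and filler class carrying an exactly-one
    constraint: when two or more fillers of that class are present and their
    classes are pairwise subsumption-comparable, they must denote the same
    individual and are merged. Incomparable fillers are left alone (they are
    not provably identical); *disjoint* fillers under an exactly-one
    constraint are a genuine contradiction and raise
    :class:`ConsistencyError`. The operation is idempotent and mutates
    ``graph`` in place (also returning it).
    """
    changed = True
    while changed:
        changed = False
        for (cls, rel, filler), cc in sorted(kb.constraints.items()):
            if not (cc.is_exact and cc.min == 1):
                continue
            for ind in graph.instances_of(kb, cls):
                fillers = sorted({
                    o for (s, r, o) in graph.triples
                    if s == ind.id and r == rel
                    and any(kb.is_subclass_of(lbl, filler)
                            for lbl in graph.individuals[o].class_labels)
                })
                if len(fillers) < 2:
                    continue
                labels = {f: graph.individuals[f].most_specific_labels(kb) for f in fillers}
                comparable = True
                for i, a in enumerate(fillers):
                    for b in fillers[i + 1:]:
                        for la in labels[a]:
                            for lb in labels[b]:
                                if kb.disjoint(la, lb):
                                    raise ConsistencyError(
                                        f"exactly-1 {rel} {filler} on {ind.id}: disjoint fillers "
                                        f"{a!r} ({la}) and {b!r} ({lb})"
                                    )
                                if not kb.comparable(la, lb):
                                    comparable = False
                if not comparable:
                    continue
                _merge_in_graph(graph, fillers)
                changed = True
                break  # triples changed; recompute
            if changed:
                break
    return graph


def _merge_in_graph(graph: InstanceGraph, ids: list[str]) -> str:
    keep = ids[0]
    kept = graph.individuals[keep]
    for other in ids[1:]:
        kept.class_labels |= graph.individuals[other].class_labels
        del graph.individuals[other]
    mapping = {i: keep for i in ids[1:]}

    def m(i: str) -> str:
        return mapping.get(i, i)

    new_triples = {(m(s), r, m(o)) for (s, r, o) in graph.triples}
    new_prov = {}
    for (s, r, o), p in graph.provenance.items():
        new_prov.setdefault((m(s), r, m(o)), p)
    graph.triples = new_triples
    graph.provenance = new_prov
    graph.property_values = {(m(s), p, lit) for (s, p, lit) in graph.property_values}
    return keep


# ---------------------------------------------------------------------------
# Q1: relation values (and the during variant)


def _seed_of(graph: InstanceGraph, cls: str) -> str:
    for ind in sorted(graph.individuals.values(), key=lambda i: i.id):
        if ind.origin == "seed" and cls in ind.class_labels:
            return ind.id
    raise KBError(f"graph has no seed individual of class {cls!r}")


def query_relation_values(
    kb: KnowledgeBase,
    cls: str,
    relation: str,
    expand: bool = False,
    depth: int = DEFAULT_DEPTH,
) -> set[tuple[str, str]]:
    """Fillers of ``relation`` on a sample instance of ``cls``.

    Returns ``(filler class, via-relation)`` pairs, the filler class being
    the most specific label of the filler individual (after equality
    merging). With ``expand``, the whole sub-relation subtree of ``relation``
    is queried and each answer is tagged with the sub-relation it actually
    came through -- this is how "what is the structure of X?" fans out over
    has-part, has-region, material and possesses.
    """
    if cls not in kb.classes:
        raise KBError(f"unknown class {cls!r}")
    rels = kb.subrelations(relation) if expand else {relation}
    if relation not in kb.relations:
        raise KBError(f"unknown relation {relation!r}")
    graph = elaborate(kb, cls, depth)
    seed = _seed_of(graph, cls)
    out: set[tuple[str, str]] = set()
    for s, r, o in graph.outgoing(seed, rels):
        for label in graph.individuals[o].most_specific_labels(kb):
            out.add((label, r))
    return out


def spatial_relations_among(
    kb: KnowledgeBase, cls: str, depth: int = DEFAULT_DEPTH
) -> set[tuple[str, str, str]]:
    """Spatial triples among the structural fillers of ``cls``, as
    (subject class, spatial relation, object class); completes a structural
    description the way "what is the structure of X?" is answered."""
    graph = elaborate(kb, cls, depth)
    seed = _seed_of(graph, cls)
    structural = {o for _, _, o in graph.outgoing(seed, kb.subrelations("has-structure"))}
    spatial = {r.name for r in kb.relations.values() if r.kind is RelationKind.SPATIAL}
    out = set()
    for s, r, o in sorted(graph.triples):
        if r in spatial and s in structural and o in structural:
            for ls in graph.individuals[s].most_specific_labels(kb):
                for lo in graph.individuals[o].most_specific_labels(kb):
                    out.add((ls, r, lo))
    return out


def query_during(
    kb: KnowledgeBase,
    entity_cls: str,
    event_cls: str,
    role: str,
    depth: int = DEFAULT_DEPTH,
) -> set[str]:
    """Events among the sub-steps of ``event_cls`` in which ``entity_cls``
    fills ``role`` ("what does X do during Y?").

    Steps are the instances of ``event_cls`` (itself included) plus their
    subevent closure in the combined elaboration of both classes.
    """
    for name in (entity_cls, event_cls):
        if name not in kb.classes:
            raise KBError(f"unknown class {name!r}")
    if role not in kb.relations:
        raise KBError(f"unknown relation {role!r}")
    if not kb.is_subclass_of(event_cls, "Event"):
        raise KBError(f"{event_cls!r} is not an Event")
    graph = elaborate(kb, entity_cls, depth)
    if event_cls != entity_cls:
        elaborate(kb, event_cls, depth, graph=graph)
    steps: set[str] = {i.id for i in graph.instances_of(kb, event_cls)}
    frontier = list(steps)
    while frontier:
        cur = frontier.pop()
        for _, r, o in graph.outgoing(cur, {"subevent"} & set(kb.relations)):
            if o not in steps:
                steps.add(o)
                frontier.append(o)
    out: set[str] = set()
    for e in sorted(steps):
        for _, _, o in graph.outgoing(e, {role}):
            if any(kb.is_subclass_of(lbl, entity_cls) for lbl in graph.individuals[o].class_labels):
                out |= graph.individuals[e].most_specific_labels(kb)
    return out


# ---------------------------------------------------------------------------
# Q2: taxonomy


def taxonomy_query(
    kb: KnowledgeBase,
    cls: str,
    mode: Literal["subclasses", "superclasses"] = "subclasses",
    *,
    other: Optional[str] = None,
) -> Union[set[str], bool]:
    """Transitive taxonomy closure; with ``other`` set, the reflexive
    subclass test ``cls is a subclass of other``."""
    if cls not in kb.classes:
        raise KBError(f"unknown class {cls!r}")
    if other is not None:
        if other not in kb.classes:
            raise KBError(f"unknown class {other!r}")
        return kb.is_subclass_of(cls, other)
    if mode == "subclasses":
        return kb.subclasses(cls)
    if mode == "superclasses":
        return kb.superclasses(cls)
    raise KBError(f"unknown taxonomy mode {mode!r}")


# ---------------------------------------------------------------------------
# Q3: cardinality lookup


def cardinality_query(
    kb: KnowledgeBase, cls: str, relation: str, filler: str
) -> Optional[CardinalityConstraint]:
    """Most specific cardinality constraint for (cls, relation, filler).

    The class's superclass chain is walked breadth-first from ``cls``; at
    each level, standalone constraints and cardinality-annotated rule edges
    whose subject node is of that class are consulted. A subclass constraint
    therefore overrides a superclass one. Returns None when unconstrained.
    """
    for name in (cls, filler):
        if name not in kb.classes:
            raise KBError(f"unknown class {name!r}")
    if relation not in kb.relations:
        raise KBError(f"unknown relation {relation!r}")
    level = [cls]
    seen = set(level)
    while level:
        found: list[CardinalityConstraint] = []
        for c in sorted(level):
            cc = kb.constraints.get((c, relation, filler))
            if cc is not None:
                found.append(cc)
            for rule in kb.iter_rules():
                for e in rule.edges:
                    if (e.cardinality is not None and e.relation == relation
                            and rule.node(e.subject).class_label == c
                            and rule.node(e.object).class_label == filler):
                        found.append(e.cardinality)
        if found:
            return found[0]
        nxt = []
        for c in level:
            for p in sorted(kb.classes[c].parents):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        level = nxt
    return None


# ---------------------------------------------------------------------------
# Q4: describe


def describe(kb: KnowledgeBase, cls: str, depth: int = DEFAULT_DEPTH) -> Description:
    """Concept description: exactly the union of the taxonomy, relation-value
    and cardinality sub-queries, organized into one result object."""
    if cls not in kb.classes:
        raise KBError(f"unknown class {cls!r}")
    sups = taxonomy_query(kb, cls, "superclasses")
    subs = taxonomy_query(kb, cls, "subclasses")
    graph = elaborate(kb, cls, depth)
    seed = _seed_of(graph, cls)
    values: dict[str, set[str]] = {}
    for _, r, o in graph.outgoing(seed):
        values.setdefault(r, set()).update(graph.individuals[o].most_specific_labels(kb))
    cards: dict[tuple[str, str], CardinalityConstraint] = {}
    for r, fillers in values.items():
        for f in fillers:
            cc = cardinality_query(kb, cls, r, f)
            if cc is not None:
                cards[(r, f)] = cc
    for (c, r, f), _cc in kb.constraints.items():
        if kb.is_subclass_of(cls, c):
            cc = cardinality_query(kb, cls, r, f)
            if cc is not None:
                cards[(r, f)] = cc
    return Description(
        cls=cls,
        superclasses=frozenset(sups),
        subclasses=frozenset(subs),
        relation_values=tuple(sorted((r, frozenset(v)) for r, v in values.items())),
        cardinalities=tuple(sorted(cards.items())),
    )


# ---------------------------------------------------------------------------
# Q5: compare


def compare(
    kb: KnowledgeBase, x: str, y: str, restrict_to: Optional[str] = None,
    depth: int = DEFAULT_DEPTH,
) -> ComparisonResult:
    """Similarities and differences between the descriptions of two classes.

    Slots are aligned by relation name; within a shared slot, fillers are
    aligned greedily, exact class matches first, then by deepest common
    ancestor. Aligned equal fillers are similarities; aligned distinct
    fillers and unmatched fillers are differences; slots present in only one
    description are reported separately. ``restrict_to`` limits the
    comparison to a relation subtree (e.g. ``has-structure`` for "what are
    the structural differences?").
    """
    dx = describe(kb, x, depth)
    dy = describe(kb, y, depth)
    allowed = kb.subrelations(restrict_to) if restrict_to is not None else None
    vx = {r: set(v) for r, v in dx.relation_values if allowed is None or r in allowed}
    vy = {r: set(v) for r, v in dy.relation_values if allowed is None or r in allowed}
    sims: list[tuple[str, str]] = []
    diffs: list[tuple[str, Optional[str], Optional[str]]] = []
    for rel in sorted(set(vx) & set(vy)):
        fx, fy = set(vx[rel]), set(vy[rel])
        candidates = []
        for a in sorted(fx):
            for b in sorted(fy):
                dca = kb.deepest_common_ancestor(a, b)
                if dca is not None:
                    pair = tuple(sorted((a, b)))
                    candidates.append((a != b, -kb.class_depth(dca), pair, a, b, dca))
        candidates.sort()
        for _, _, _, a, b, dca in candidates:
            if a in fx and b in fy:
                fx.discard(a)
                fy.discard(b)
                if a == b:
                    sims.append((rel, a))
                else:
                    diffs.append((rel, a, b))
        for a in sorted(fx):
            diffs.append((rel, a, None))
        for b in sorted(fy):
            diffs.append((rel, None, b))
    only_x = tuple(sorted(set(vx) - set(vy)))
    only_y = tuple(sorted(set(vy) - set(vx)))
    for rel in only_x:
        for a in sorted(vx[rel]):
            diffs.append((rel, a, None))
    for rel in only_y:
        for b in sorted(vy[rel]):
            diffs.append((rel, None, b))
    return ComparisonResult(
        x=x, y=y,
        similarities=tuple(sorted(sims)),
        differences=tuple(sorted(diffs, key=lambda d: (d[0], d[1] or "", d[2] or ""))),
        slots_only_in_x=only_x,
        slots_only_in_y=only_y,
    )


# ---------------------------------------------------------------------------
# Q6: relationship paths, analogy, importance


def _relation_priority(kb: KnowledgeBase, rel: str) -> int:
    if rel in (SUBCLASS_OF, SUPERCLASS_OF):
        return 0
    return _KIND_PRIORITY.get(kb.relations[rel].kind, 4)


def _rank_key(kb: KnowledgeBase, path: Path):
    return (
        len(path),
        tuple(_relation_priority(kb, r) for r in path.relations),
        path.relations,
    )


def _graph_paths(
    kb: KnowledgeBase,
    graph: InstanceGraph,
    start: str,
    targets: set[str],
    max_depth: int,
    *,
    required_relation: Optional[str] = None,
) -> list[Path]:
    """All simple triple-paths from ``start`` to any target individual,
    truncated at the first target on the path, up to ``max_depth`` hops."""
    mg = nx.MultiDiGraph()
    mg.add_nodes_from(graph.individuals)
    for s, r, o in sorted(graph.triples):
        mg.add_edge(s, o, key=r)
    required = kb.subrelations(required_relation) if required_relation else None
    out: list[Path] = []
    for target in sorted(targets):
        if target == start:
            continue
        for edge_path in nx.all_simple_edge_paths(mg, start, target, cutoff=max_depth):
            nodes = [o for _, o, _ in edge_path[:-1]]
            if any(n in targets for n in nodes):
                continue  # stop at the first encountered instance of Y
            triples = tuple((s, r, o) for s, o, r in [(u, v, k) for u, v, k in edge_path])
            if required is not None and not any(r in required for _, r, _ in triples):
                continue
            out.append(Path(triples))
    return sorted(set(out), key=lambda p: _rank_key(kb, p))


def find_relationship(
    kb: KnowledgeBase, x: str, y: str, max_depth: int = DEFAULT_DEPTH
) -> list[Path]:
    """Relationship paths from a sample instance of ``x`` to instances of
    ``y`` ("what is the relationship between X and Y?").

    Taxonomic links are searched first (a direct sub/superclass chain is
    reported as a path over the ``subclass-of``/``superclass-of``
    pseudo-relations); then the elaborated instance graph of ``x`` is
    searched best-first for triple-paths ending at the first instance of
    ``y`` encountered. All paths up to ``max_depth`` are returned ranked by
    length, then relation priority, then lexicographically. An empty result
    is a valid answer.
    """
    for name in (x, y):
        if name not in kb.classes:
            raise KBError(f"unknown class {name!r}")
    if max_depth < 1:
        raise KBError(f"max_depth must be >= 1, got {max_depth}")
    if x == y:
        return [Path(())]
    paths: list[Path] = []
    paths.extend(_taxonomy_paths(kb, x, y, max_depth))
    graph = elaborate(kb, x, max_depth)
    seed = _seed_of(graph, x)
    targets = {i.id for i in graph.instances_of(kb, y)}
    paths.extend(_graph_paths(kb, graph, seed, targets, max_depth))
    return sorted(set(paths), key=lambda p: _rank_key(kb, p))


def _taxonomy_paths(kb: KnowledgeBase, x: str, y: str, max_depth: int) -> list[Path]:
    def chains(start: str, end: str, up: bool) -> list[tuple[str, ...]]:
        rel = SUBCLASS_OF if up else SUPERCLASS_OF
        out = []
        stack: list[tuple[str, tuple]] = [(start, ())]
        while stack:
            cur, trail = stack.pop()
            if cur == end and trail:
                out.append(trail)
                continue
            if len(trail) >= max_depth:
                continue
            steps = kb.classes[cur].parents if up else {
                c for c in kb.classes if cur in kb.classes[c].parents
            }
            for nxt in sorted(steps):
                stack.append((nxt, trail + ((cur, rel, nxt),)))
        return out

    paths = []
    if y in kb.superclasses(x):
        paths += [Path(t) for t in chains(x, y, up=True)]
    elif y in kb.subclasses(x):
        paths += [Path(t) for t in chains(x, y, up=False)]
    return paths


def analogy(
    kb: KnowledgeBase, x: str, y: str, a: str, max_depth: int = DEFAULT_DEPTH
) -> set[str]:
    """Answer "X is to Y as A is to what?".

    Computes the relationship paths from X to Y, then replays each path's
    relation signature starting from a sample instance of A; the classes
    reached are the answers (empty when no signature is traversable).
    """
    for name in (x, y, a):
        if name not in kb.classes:
            raise KBError(f"unknown class {name!r}")
    signatures: list[tuple[str, ...]] = []
    for p in find_relationship(kb, x, y, max_depth):
        if p.relations and p.relations not in signatures:
            signatures.append(p.relations)
    out: set[str] = set()
    graph = elaborate(kb, a, max_depth)
    seed = _seed_of(graph, a)
    for sig in signatures:
        if all(r in (SUBCLASS_OF, SUPERCLASS_OF) for r in sig):
            frontier = {a}
            for r in sig:
                step: set[str] = set()
                for c in frontier:
                    step |= (kb.classes[c].parents if r == SUBCLASS_OF
                             else {s for s in kb.classes if c in kb.classes[s].parents})
                frontier = step
            out |= frontier
            continue
        frontier_ids = {seed}
        for r in sig:
            step_ids: set[str] = set()
            for i in frontier_ids:
                step_ids |= {o for _, _, o in graph.outgoing(i, {r})}
            frontier_ids = step_ids
            if not frontier_ids:
                break
        for i in frontier_ids:
            out |= graph.individuals[i].most_specific_labels(kb)
    return out


def trace_importance(
    kb: KnowledgeBase, x: str, prop: str, max_depth: int = 4
) -> list[Path]:
    """Why is it important that ``x`` has ``prop``?

    Finds paths that begin at the property (a quality individual possessed
    by the sample instance, or the filler of a property relation), end at a
    function of ``x`` (a ``has-function`` filler), and pass through the
    ``facilitates`` relation; same machinery and ranking as relationship
    search otherwise.
    """
    if x not in kb.classes:
        raise KBError(f"unknown class {x!r}")
    graph = elaborate(kb, x, max_depth)
    seed = _seed_of(graph, x)
    starts: set[str] = set()
    if prop in kb.relations:
        starts = {o for _, _, o in graph.outgoing(seed, {prop})}
    elif prop in kb.classes:
        starts = {
            o for _, _, o in graph.outgoing(seed, {"possesses"} & set(kb.relations))
            if any(kb.is_subclass_of(lbl, prop) for lbl in graph.individuals[o].class_labels)
        }
    else:
        raise KBError(f"unknown property {prop!r}")
    targets = {o for _, _, o in graph.outgoing(seed, {"has-function"} & set(kb.relations))}
    out: list[Path] = []
    for start in sorted(starts):
        out.extend(
            _graph_paths(kb, graph, start, targets, max_depth, required_relation="facilitates")
        )
    return sorted(set(out), key=lambda p: _rank_key(kb, p))
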