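"""Brute-force reference implementations and a synthetic KB generator.

The oracles deliberately share no machinery with :mod:`biokr.reasoner`: the
materializer applies every rule with *fresh* individuals and then merges
exhaustively (by ground Skolem-term identity and by declared equalities)
until fixpoint, and the path enumerator is a plain recursive DFS. They
ignore all ranking heuristics, so comparisons against the reasoner are on
answer *sets*. Both carry documented soft limits -- they exist for small
knowledge bases only.

The generator draws random but always-valid knowledge bases (they load
through the native-format round-trip) whose shape is controlled by
:class:`SynthParams`; the cross-edge probability controls the fraction of
non-tree rules, which is what the OWL-export loss accounting is tested
against.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .kb_core import (
    CardinalityConstraint,
    ClassDef,
    EqualityStatement,
    GraphRule,
    Individual,
    InstanceGraph,
    KBError,
    KnowledgeBase,
    Quantifier,
    RelationDef,
    RelationKind,
    RuleEdge,
    RuleNode,
    SkolemizedRule,
    skolemize,
)

__all__ = [
    "SynthParams",
    "OracleLimitError",
    "materialize_bruteforce",
    "enumerate_paths_bruteforce",
    "oracle_relation_values",
    "oracle_cardinality_query",
    "path_fingerprint",
    "generate_synthetic_kb",
]

#: Soft limits for the brute-force materializer.
MAX_ORACLE_INDIVIDUALS = 3000
MAX_ORACLE_ROUNDS = 200


class OracleLimitError(KBError):
    """The knowledge base is too large for the brute-force oracle."""


# ---------------------------------------------------------------------------
# Brute-force materialization


def materialize_bruteforce(kb: KnowledgeBase, cls: str, depth: int) -> InstanceGraph:
    """Naive fixpoint elaboration: fresh individuals, then exhaustive merging.

    Semantically equivalent to :func:`biokr.reasoner.elaborate` for every
    query, but computed the slow way: each rule application mints brand-new
    individuals; afterwards, individuals whose ground Skolem terms coincide
    (same function, same scope, same -- merged -- root) or that are linked by
    a declared equality are merged, and the apply/merge loop repeats until
    nothing changes.
    """
    if cls not in kb.classes:
        raise KBError(f"unknown class {cls!r}")
    serial = 0

    parent_of: dict[int, int] = {}
    labels: dict[int, set[str]] = {}
    depth_of: dict[int, int] = {}
    term_of: dict[int, tuple[str, str, int] | None] = {}  # (function, scope, root serial)

    def find(i: int) -> int:
        while parent_of[i] != i:
            parent_of[i] = parent_of[parent_of[i]]
            i = parent_of[i]
        return i

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        keep, drop = min(ra, rb), max(ra, rb)
        parent_of[drop] = keep
        labels[keep] |= labels[drop]
        depth_of[keep] = min(depth_of[keep], depth_of[drop])

    def fresh(lbls: set[str], d: int, term: tuple[str, str, int] | None) -> int:
        nonlocal serial
        i = serial
        serial += 1
        parent_of[i] = i
        labels[i] = set(lbls)
        depth_of[i] = d
        term_of[i] = term
        if serial > MAX_ORACLE_INDIVIDUALS:
            raise OracleLimitError(f"more than {MAX_ORACLE_INDIVIDUALS} raw individuals")
        return i

    seed = fresh({cls}, 0, None)
    triples: list[tuple[int, str, int]] = []
    equal_pairs: list[tuple[tuple[str, str, int], tuple[str, str, int]]] = []
    props: list[tuple[int, str, str]] = []
    applied: set[tuple[int, str]] = set()

    def merge_to_fixpoint() -> None:
        # the term index is built over *all* raw individuals: a merged-away
        # individual's ground term still identifies its representative
        changed = True
        while changed:
            changed = False
            by_term: dict[tuple[str, str, int], int] = {}
            for i in sorted(parent_of):
                t = term_of[i]
                if t is None:
                    continue
                key = (t[0], t[1], find(t[2]))
                r = find(i)
                if key in by_term:
                    if find(by_term[key]) != r:
                        union(by_term[key], r)
                        changed = True
                else:
                    by_term[key] = r
            for (lf, ls, lr), (rf, rs, rr) in equal_pairs:
                li = by_term.get((lf, ls, find(lr)))
                ri = by_term.get((rf, rs, find(rr)))
                if li is not None and ri is not None and find(li) != find(ri):
                    union(li, ri)
                    changed = True

    rounds = 0
    while True:
        rounds += 1
        if rounds > MAX_ORACLE_ROUNDS:
            raise OracleLimitError("apply/merge loop did not converge")
        merge_to_fixpoint()
        did_apply = False
        for i in sorted(parent_of):
            if parent_of[i] != i or depth_of[i] >= depth:
                continue
            lineage: set[str] = set()
            for lbl in labels[i]:
                lineage |= kb.superclasses(lbl, reflexive=True)
            for c in sorted(lineage):
                for rule in sorted(kb.rules.get(c, []), key=lambda r: r.rule_id):
                    if (i, rule.rule_id) in applied:
                        continue
                    applied.add((i, rule.rule_id))
                    did_apply = True
                    ground: dict[str, int] = {rule.root_var: i}
                    for var, term in rule.terms:
                        node = rule.node(var)
                        ground[var] = fresh(
                            {node.class_label}, depth_of[i] + 1,
                            (term.function_name, term.scope, i),
                        )
                    for e in rule.edges:
                        triples.append((ground[e.subject], e.relation, ground[e.object]))
                    for var, prop, lit in rule.property_assertions:
                        props.append((ground[var], prop, lit))
                    for eq in rule.equalities:
                        equal_pairs.append((
                            (eq.left.function_name, eq.left.scope, i),
                            (eq.right.function_name, eq.right.scope, i),
                        ))
        if not did_apply:
            break

    # A merge can reveal new labels on an already-processed individual whose
    # rules then still need applying; the outer loop re-checks, and `applied`
    # is keyed by raw serials, so re-application after a merge creates
    # duplicate raw individuals that the next merge pass collapses.

    from .kb_core import SkolemTerm

    graph = InstanceGraph()
    rep_ids: dict[int, str] = {}
    for i in sorted(parent_of):
        if parent_of[i] == i:
            rep_ids[i] = f"i{i}"
            t = term_of[i]
            origin = "seed" if t is None else SkolemTerm(t[0], "x", t[1])
            graph.individuals[f"i{i}"] = Individual(f"i{i}", origin, set(labels[i]))
    graph.individuals[rep_ids[find(seed)]].origin = "seed"
    for s, r, o in triples:
        graph.add_triple(rep_ids[find(s)], r, rep_ids[find(o)], "bruteforce")
    for s, p, lit in props:
        graph.property_values.add((rep_ids[find(s)], p, lit))
    graph.close_inverses(kb)
    return graph


def oracle_relation_values(
    kb: KnowledgeBase, cls: str, relation: str, expand: bool, depth: int
) -> set[tuple[str, str]]:
    """Q1 computed on the brute-force materialization."""
    graph = materialize_bruteforce(kb, cls, depth)
    seed = next(i.id for i in graph.individuals.values() if i.origin == "seed")
    rels = kb.subrelations(relation) if expand else {relation}
    out: set[tuple[str, str]] = set()
    for s, r, o in graph.triples:
        if s != seed or r not in rels:
            continue
        for label in graph.individuals[o].most_specific_labels(kb):
            out.add((label, r))
    return out


def oracle_cardinality_query(kb: KnowledgeBase, cls: str, relation: str, filler: str):
    """Q3 by explicit level-by-level enumeration of the superclass chain."""
    levels: list[list[str]] = [[cls]]
    seen = {cls}
    while True:
        nxt: list[str] = []
        for c in levels[-1]:
            for p in sorted(kb.classes[c].parents):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        if not nxt:
            break
        levels.append(nxt)
    edge_constraints: dict[str, list[CardinalityConstraint]] = {}
    for rule in kb.iter_rules():
        for e in rule.edges:
            if e.cardinality is not None and e.relation == relation:
                if rule.node(e.object).class_label == filler:
                    edge_constraints.setdefault(rule.node(e.subject).class_label, []).append(e.cardinality)
    for level in levels:
        hits: list[CardinalityConstraint] = []
        for c in sorted(level):
            if (c, relation, filler) in kb.constraints:
                hits.append(kb.constraints[(c, relation, filler)])
            hits.extend(edge_constraints.get(c, []))
        if hits:
            return hits[0]
    return None


# ---------------------------------------------------------------------------
# Brute-force path enumeration


def enumerate_paths_bruteforce(
    kb: KnowledgeBase, x: str, y: str, max_depth: int
) -> list[tuple[tuple[str, str, str], ...]]:
    """All simple triple-paths from a sample instance of ``x`` to the first
    encountered instance of ``y``, by exhaustive DFS on the brute-force
    materialization. Returns raw triple tuples (unranked)."""
    graph = materialize_bruteforce(kb, x, max_depth)
    seed = next(i.id for i in graph.individuals.values() if i.origin == "seed")
    targets = {
        i.id for i in graph.individuals.values()
        if any(kb.is_subclass_of(lbl, y) for lbl in i.class_labels)
    }
    out: list[tuple[tuple[str, str, str], ...]] = []

    def dfs(node: str, visited: set[str], trail: tuple[tuple[str, str, str], ...]) -> None:
        if len(trail) >= max_depth:
            return
        for s, r, o in sorted(graph.triples):
            if s != node or o in visited:
                continue
            step = trail + ((s, r, o),)
            if o in targets:
                out.append(step)
                continue  # stop at the first instance of y
            dfs(o, visited | {o}, step)

    dfs(seed, {seed}, ())
    return out


def path_fingerprint(kb: KnowledgeBase, graph: InstanceGraph, triples) -> tuple:
    """Identity of a path independent of individual ids: the alternating
    sequence of node label sets and relation names."""
    if not triples:
        return ()
    items: list = [frozenset(graph.individuals[triples[0][0]].most_specific_labels(kb))]
    for s, r, o in triples:
        items.append(r)
        items.append(frozenset(graph.individuals[o].most_specific_labels(kb)))
    return tuple(items)


# ---------------------------------------------------------------------------
# Synthetic KB generation


@dataclass(frozen=True)
class SynthParams:
    """Shape parameters for random knowledge bases (same seed, same KB)."""

    n_classes: int = 6
    n_relations: int = 4
    rules_per_class: int = 1
    max_nodes_per_rule: int = 4
    cross_edge_prob: float = 0.3
    equality_prob: float = 0.3
    constraint_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_relations", "rules_per_class", "max_nodes_per_rule"):
            if getattr(self, name) < 1:
                raise KBError(f"{name} must be positive")
        for name in ("cross_edge_prob", "equality_prob", "constraint_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise KBError(f"{name} must be in [0, 1]")


def generate_synthetic_kb(params: SynthParams) -> KnowledgeBase:
    """Draw a random valid knowledge base.

    Rules are built as a root-directed spanning tree plus optional cross
    edges, so with ``cross_edge_prob == 0`` every rule is tree-shaped and
    with ``cross_edge_prob == 1`` every rule with at least two non-root
    nodes is not. Equalities (drawn with ``equality_prob``) link a rule's
    node to a subsumption-comparable node of a strict-ancestor rule, which
    is the shape inheritance specialization takes.
    """
    rng = random.Random(params.seed)
    kb = KnowledgeBase()

    class_names = [f"Syn-C{i}" for i in range(params.n_classes)]
    classes = []
    for i, name in enumerate(class_names):
        parents: frozenset[str] = frozenset()
        if i > 0 and rng.random() < 0.7:
            parents = frozenset({class_names[rng.randrange(i)]})
        classes.append(ClassDef(name, parents))
    kb.add_class(classes)

    rel_names = [f"syn-r{i}" for i in range(params.n_relations)]
    kinds = [RelationKind.STRUCTURAL, RelationKind.SPATIAL,
             RelationKind.PARTICIPANT, RelationKind.FUNCTIONAL]
    rels = []
    for i, name in enumerate(rel_names):
        parent = rel_names[rng.randrange(i)] if i > 0 and rng.random() < 0.4 else None
        rels.append(RelationDef(name, rng.choice(kinds), parent))
    rels.append(RelationDef("syn-p0", RelationKind.PROPERTY))
    kb.add_relation(rels)

    rule_count = 0
    rules_by_class: dict[str, list[SkolemizedRule]] = {}
    for cls in class_names:
        n_rules = rng.randint(0, params.rules_per_class)
        for _ in range(n_rules):
            rule_count += 1
            rule = _random_rule(kb, rng, cls, f"syn-rule-{rule_count}", rel_names, class_names, params)
            kb.add_rule(rule)
            rules_by_class.setdefault(cls, []).append(rule)
    if rule_count == 0:
        rule = _random_rule(kb, rng, class_names[0], "syn-rule-1", rel_names, class_names, params)
        kb.add_rule(rule)
        rules_by_class.setdefault(class_names[0], []).append(rule)

    # equalities: subclass rule node == comparable ancestor rule node
    for cls in class_names:
        for rule in rules_by_class.get(cls, []):
            if rng.random() >= params.equality_prob:
                continue
            ancestors = sorted(kb.superclasses(cls))
            anc_rules = [r for a in ancestors for r in rules_by_class.get(a, [])]
            options = []
            for other in anc_rules:
                for lv, lt in rule.terms:
                    for rv, rt in other.terms:
                        la = rule.node(lv).class_label
                        lb = other.node(rv).class_label
                        if kb.comparable(la, lb) and not kb.disjoint(la, lb):
                            options.append(EqualityStatement(lt, rt))
            if options:
                kb.attach_equalities(rule.rule_id, (rng.choice(options),))

    n_constraints = sum(1 for _ in class_names if rng.random() < params.constraint_prob)
    for _ in range(n_constraints):
        cls = rng.choice(class_names)
        rel = rng.choice(rel_names)
        filler = rng.choice(class_names)
        kind = rng.random()
        if kind < 0.5:
            cc = CardinalityConstraint.exactly(rng.randint(0, 3))
        else:
            cc = CardinalityConstraint(rng.randint(0, 2), None)
        kb.add_constraint(cls, rel, filler, cc)
    return kb


def _random_rule(
    kb: KnowledgeBase,
    rng: random.Random,
    cls: str,
    rule_id: str,
    rel_names: list[str],
    class_names: list[str],
    params: SynthParams,
) -> SkolemizedRule:
    n_nodes = rng.randint(1, params.max_nodes_per_rule)
    nodes = [RuleNode("x", cls, Quantifier.UNIVERSAL_ROOT)]
    for j in range(1, n_nodes):
        nodes.append(RuleNode(f"v{j}", rng.choice(class_names)))
    edges: list[RuleEdge] = []
    for j in range(1, n_nodes):
        parent = nodes[rng.randrange(j)].var_id
        edges.append(RuleEdge(parent, rng.choice(rel_names), nodes[j].var_id))
    if n_nodes >= 2 and rng.random() < params.cross_edge_prob:
        cross = _pick_cross_edge(rng, nodes, edges, rel_names)
        if cross is not None:
            edges.append(cross)
    props: list[tuple[str, str, str]] = []
    if rng.random() < 0.2:
        props.append((rng.choice(nodes).var_id, "syn-p0", rng.choice(["weak", "strong"])))
    if n_nodes >= 2 and rng.random() < 0.3:
        e = rng.randrange(len(edges))
        edges[e] = RuleEdge(
            edges[e].subject, edges[e].relation, edges[e].object,
            CardinalityConstraint.exactly(rng.randint(1, 3)),
        )
    return skolemize(GraphRule(rule_id, cls, tuple(nodes), tuple(edges), tuple(props)))


def _pick_cross_edge(rng, nodes, edges, rel_names):
    existing = {(e.subject, e.relation, e.object) for e in edges}
    options = []
    for a in nodes:
        for b in nodes:
            if a.var_id == b.var_id:
                continue
            for rel in rel_names:
                if (a.var_id, rel, b.var_id) not in existing:
                    options.append(RuleEdge(a.var_id, rel, b.var_id))
    return rng.choice(options) if options else None
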