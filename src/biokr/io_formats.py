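"""Reading and writing knowledge bases.

Three concrete syntaxes are supported:

* the **native dialect** -- a line-oriented, diff-friendly text format in
  which the bundled fixtures are stored (grammar below);
* **OWL2 functional syntax** -- a *lossy* export: each rule becomes a
  subclass axiom whose superclass nests existential restrictions along a
  breadth-first spanning tree of the rule graph; cross-edges (the ones that
  violate the tree model property) and Skolem-term equalities cannot be
  expressed and are dropped, with every drop recorded in a
  :class:`LossReport`;
* a **TPTP-style first-order export** -- non-lossy: Skolem terms, equality
  statements, relation metadata and cardinality constraints are all
  preserved, and :func:`parse_fol` reconstructs an isomorphic knowledge base
  from the exported text.

Native dialect grammar (one declaration per line; ``;`` starts a comment;
identifiers match ``[A-Za-z0-9][A-Za-z0-9-]*``)::

    class <Name> [is-a <Parent> ...] [disjoint-with <Class> ...]
    relation <name> [kind <kind>] [parent <relation>] [inverse <relation>]
    constraint <Class> <relation> <FillerClass> <cardinality>
    rule <rule-id> of <RootClass>
      node <var> <Class> [root]
      edge <var> <relation> <var> [<cardinality>]
      prop <var> <property-relation> <literal>
      equal <var> = <rule-id>.<skolem-function>
    end

where ``<cardinality>`` is ``exactly <n>``, ``min <n>``, ``max <n>`` or
``<min>..<max|*>``. Exactly one node per rule carries ``root``. Equality
lines state that this rule's Skolem term for ``<var>`` denotes the same
individual as the named Skolem function of another rule in the same subclass
lineage.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Optional

from .kb_core import (
    CardinalityConstraint,
    ClassDef,
    EqualityStatement,
    GraphRule,
    KBError,
    KnowledgeBase,
    Quantifier,
    RelationDef,
    RelationKind,
    RuleEdge,
    RuleNode,
    SkolemTerm,
    SkolemizedRule,
    check_tree_model,
    skolemize,
)

__all__ = [
    "KBSyntaxError",
    "LossReport",
    "parse_kb",
    "serialize_kb",
    "export_owl2_functional",
    "export_fol",
    "parse_fol",
    "canonical_rule_form",
    "kb_isomorphic",
]

_IDENT = r"[A-Za-z0-9][A-Za-z0-9-]*"
_IDENT_RE = re.compile(rf"^{_IDENT}$")


class KBSyntaxError(KBError):
    """Syntax or referential-integrity error with source position."""

    def __init__(self, message: str, line: int, column: int = 1) -> None:
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


@dataclass(frozen=True)
class LossReport:
    """What the OWL2 export could not express."""

    rules_exported: int
    non_tree_rules: int
    dropped_edges: tuple[tuple[str, str, str, str], ...]  # (rule id, subject, relation, object)
    equalities_dropped: int

    @property
    def is_lossy(self) -> bool:
        return bool(self.dropped_edges) or self.equalities_dropped > 0


# ---------------------------------------------------------------------------
# Native dialect: parsing


def _parse_cardinality(tokens: list[str], line: int) -> CardinalityConstraint:
    try:
        if tokens[0] == "exactly":
            return CardinalityConstraint.exactly(int(tokens[1]))
        if tokens[0] == "min":
            return CardinalityConstraint(int(tokens[1]), None)
        if tokens[0] == "max":
            return CardinalityConstraint(0, int(tokens[1]))
        if len(tokens) == 1 and ".." in tokens[0]:
            lo, hi = tokens[0].split("..", 1)
            return CardinalityConstraint(int(lo), None if hi == "*" else int(hi))
    except (ValueError, IndexError):
        pass
    raise KBSyntaxError(f"malformed cardinality {' '.join(tokens)!r}", line)


def _split_line(raw: str) -> list[tuple[str, int]]:
    """Tokenize one line, dropping ``;`` comments; returns (token, column)."""
    code = raw.split(";", 1)[0]
    out = []
    for m in re.finditer(r"\S+", code):
        out.append((m.group(), m.start() + 1))
    return out


@dataclass
class _RawRule:
    rule_id: str
    root_class: str
    line: int
    nodes: list[RuleNode] = field(default_factory=list)
    edges: list[RuleEdge] = field(default_factory=list)
    props: list[tuple[str, str, str]] = field(default_factory=list)
    # (var, target rule id, target function name, line)
    equalities: list[tuple[str, str, str, int]] = field(default_factory=list)


def parse_kb(text: str, base: Optional[KnowledgeBase] = None) -> KnowledgeBase:
    """Parse native-dialect text into a :class:`KnowledgeBase`.

    ``base`` supplies an already-loaded layer (e.g. the upper ontology) whose
    declarations the parsed document may reference; the result contains both.
    Syntax errors carry line/column; referential-integrity errors name the
    offending identifier.
    """
    classes: list[tuple[ClassDef, int]] = []
    relations: list[tuple[RelationDef, int]] = []
    constraints: list[tuple[str, str, str, CardinalityConstraint, int]] = []
    rules: list[_RawRule] = []
    current: Optional[_RawRule] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = _split_line(raw)
        if not tokens:
            continue
        words = [t for t, _ in tokens]
        head, col0 = tokens[0]

        if current is not None:
            if head == "end":
                rules.append(current)
                current = None
            elif head == "node":
                if len(words) not in (3, 4) or (len(words) == 4 and words[3] != "root"):
                    raise KBSyntaxError("expected: node <var> <Class> [root]", lineno, col0)
                q = Quantifier.UNIVERSAL_ROOT if len(words) == 4 else Quantifier.EXISTENTIAL
                current.nodes.append(RuleNode(words[1], words[2], q))
            elif head == "edge":
                if len(words) < 4:
                    raise KBSyntaxError("expected: edge <var> <relation> <var> [<cardinality>]", lineno, col0)
                card = _parse_cardinality(words[4:], lineno) if len(words) > 4 else None
                current.edges.append(RuleEdge(words[1], words[2], words[3], card))
            elif head == "prop":
                if len(words) != 4:
                    raise KBSyntaxError("expected: prop <var> <relation> <literal>", lineno, col0)
                current.props.append((words[1], words[2], words[3]))
            elif head == "equal":
                if len(words) != 4 or words[2] != "=" or "." not in words[3]:
                    raise KBSyntaxError("expected: equal <var> = <rule-id>.<function>", lineno, col0)
                target_rule, target_fn = words[3].split(".", 1)
                current.equalities.append((words[1], target_rule, target_fn, lineno))
            else:
                raise KBSyntaxError(f"unexpected {head!r} inside rule block", lineno, col0)
            continue

        if head == "class":
            if len(words) < 2:
                raise KBSyntaxError("expected: class <Name> ...", lineno, col0)
            name = words[1]
            parents: set[str] = set()
            disjoint: set[str] = set()
            bucket: Optional[set[str]] = None
            for w in words[2:]:
                if w == "is-a":
                    bucket = parents
                elif w == "disjoint-with":
                    bucket = disjoint
                elif bucket is None:
                    raise KBSyntaxError(f"unexpected token {w!r} in class declaration", lineno)
                else:
                    bucket.add(w)
            classes.append((ClassDef(name, frozenset(parents), frozenset(disjoint)), lineno))
        elif head == "relation":
            if len(words) < 2:
                raise KBSyntaxError("expected: relation <name> ...", lineno, col0)
            kwargs: dict[str, str] = {}
            rest = words[2:]
            while rest:
                if len(rest) < 2 or rest[0] not in ("kind", "parent", "inverse"):
                    raise KBSyntaxError(f"unexpected token {rest[0]!r} in relation declaration", lineno)
                kwargs[rest[0]] = rest[1]
                rest = rest[2:]
            try:
                kind = RelationKind(kwargs.get("kind", "structural"))
            except ValueError:
                raise KBSyntaxError(f"unknown relation kind {kwargs['kind']!r}", lineno) from None
            relations.append(
                (RelationDef(words[1], kind, kwargs.get("parent"), kwargs.get("inverse")), lineno)
            )
        elif head == "constraint":
            if len(words) < 5:
                raise KBSyntaxError(
                    "expected: constraint <Class> <relation> <Filler> <cardinality>", lineno, col0
                )
            cc = _parse_cardinality(words[4:], lineno)
            constraints.append((words[1], words[2], words[3], cc, lineno))
        elif head == "rule":
            if len(words) != 4 or words[2] != "of":
                raise KBSyntaxError("expected: rule <rule-id> of <RootClass>", lineno, col0)
            current = _RawRule(words[1], words[3], lineno)
        else:
            raise KBSyntaxError(f"unknown declaration {head!r}", lineno, col0)

    if current is not None:
        raise KBSyntaxError(f"rule {current.rule_id!r} not closed with 'end'", current.line)

    kb = KnowledgeBase()
    if base is not None:
        kb.merge(base)
    try:
        if classes:
            kb.add_class([c for c, _ in classes])
        if relations:
            kb.add_relation([r for r, _ in relations])
    except KBError as exc:
        line = classes[0][1] if classes else 1
        raise KBSyntaxError(str(exc), line) from exc

    # Rules: Skolemize first, then resolve equalities (which may point at any
    # rule in the document or the base layer), then install.
    srules: dict[str, SkolemizedRule] = {r.rule_id: r for r in kb.iter_rules()}
    order: list[str] = []
    for rr in rules:
        rule = GraphRule(rr.rule_id, rr.root_class, tuple(rr.nodes), tuple(rr.edges), tuple(rr.props))
        problems = kb.validate_rule(rule)
        if problems:
            raise KBSyntaxError(f"rule {rr.rule_id!r}: {problems[0]}", rr.line)
        if rr.rule_id in srules:
            raise KBSyntaxError(f"duplicate rule id {rr.rule_id!r}", rr.line)
        srules[rr.rule_id] = skolemize(rule)
        order.append(rr.rule_id)

    for rule_id in order:
        try:
            kb.add_rule(srules[rule_id])
        except KBError as exc:
            line = next(r.line for r in rules if r.rule_id == rule_id)
            raise KBSyntaxError(str(exc), line) from exc

    # Equalities are attached after all rules are installed, so a statement
    # may reference any rule in the document or the base layer.
    for rr in rules:
        if not rr.equalities:
            continue
        srule = srules[rr.rule_id]
        eqs = []
        for var, target_rule, target_fn, line in rr.equalities:
            left = srule.term_map.get(var)
            if left is None:
                raise KBSyntaxError(f"equal: {var!r} is not an existential node of rule {rr.rule_id!r}", line)
            target = srules.get(target_rule)
            if target is None:
                raise KBSyntaxError(f"equal: unknown rule {target_rule!r}", line)
            try:
                right = target.term_for_function(target_fn)
                kb.attach_equalities(rr.rule_id, tuple(eqs + [EqualityStatement(left, right)]))
            except KBError as exc:
                raise KBSyntaxError(str(exc), line) from exc
            eqs.append(EqualityStatement(left, right))

    for cls, rel, filler, cc, line in constraints:
        try:
            kb.add_constraint(cls, rel, filler, cc)
        except KBError as exc:
            raise KBSyntaxError(str(exc), line) from exc
    return kb


# ---------------------------------------------------------------------------
# Native dialect: serialization


def serialize_kb(kb: KnowledgeBase) -> str:
    """Canonical native-dialect text: ``parse_kb(serialize_kb(kb)) == kb``."""
    lines: list[str] = []
    for name in sorted(kb.classes):
        c = kb.classes[name]
        parts = [f"class {name}"]
        if c.parents:
            parts.append("is-a " + " ".join(sorted(c.parents)))
        if c.disjoint_with:
            parts.append("disjoint-with " + " ".join(sorted(c.disjoint_with)))
        lines.append(" ".join(parts))
    for name in sorted(kb.relations):
        r = kb.relations[name]
        parts = [f"relation {name}", f"kind {r.kind.value}"]
        if r.parent:
            parts.append(f"parent {r.parent}")
        if r.inverse:
            parts.append(f"inverse {r.inverse}")
        lines.append(" ".join(parts))
    for (cls, rel, filler), cc in sorted(kb.constraints.items()):
        lines.append(f"constraint {cls} {rel} {filler} {_card_text(cc)}")
    for rule in kb.iter_rules():
        lines.append(f"rule {rule.rule_id} of {rule.root_class}")
        for n in rule.nodes:
            suffix = " root" if n.quantifier is Quantifier.UNIVERSAL_ROOT else ""
            lines.append(f"  node {n.var_id} {n.class_label}{suffix}")
        for e in rule.edges:
            card = f" {_card_text(e.cardinality)}" if e.cardinality else ""
            lines.append(f"  edge {e.subject} {e.relation} {e.object}{card}")
        for var, prop, lit in rule.property_assertions:
            lines.append(f"  prop {var} {prop} {lit}")
        term_map = rule.term_map
        for eq in rule.equalities:
            var = next(v for v, t in term_map.items() if t == eq.left)
            lines.append(f"  equal {var} = {eq.right.scope}.{eq.right.function_name}")
        lines.append("end")
    return "\n".join(lines) + "\n"


def _card_text(cc: CardinalityConstraint) -> str:
    if cc.is_exact:
        return f"exactly {cc.min}"
    if cc.max is None:
        return f"min {cc.min}" if cc.min else "0..*"
    return f"{cc.min}..{cc.max}"


# ---------------------------------------------------------------------------
# OWL2 functional-syntax export (lossy)

_OWL_PREFIX = "http://example.org/biokr#"


def _spanning_tree(rule: SkolemizedRule) -> tuple[list[tuple[RuleEdge, bool]], list[RuleEdge]]:
    """Breadth-first spanning tree of the rule graph rooted at the root node.

    Returns (tree edges with a forward-direction flag, cross edges). The
    traversal is over the undirected graph with lexicographic tie-breaking,
    so exports are deterministic. An edge used against its direction (object
    to subject) is marked ``forward=False`` and exported through
    ``ObjectInverseOf``.
    """
    adj: dict[str, list[tuple[str, RuleEdge, bool]]] = {n.var_id: [] for n in rule.nodes}
    for e in rule.edges:
        adj[e.subject].append((e.object, e, True))
        adj[e.object].append((e.subject, e, False))
    for v in adj:
        adj[v].sort(key=lambda t: (t[1].relation, t[0], not t[2]))
    root = rule.root_var
    visited = {root}
    tree: list[tuple[RuleEdge, bool]] = []
    used: set[int] = set()
    queue = deque([root])
    while queue:
        v = queue.popleft()
        for other, edge, forward in adj[v]:
            if other not in visited:
                visited.add(other)
                used.add(id(edge))
                tree.append((edge, forward))
                queue.append(other)
    cross = [e for e in rule.edges if id(e) not in used]
    return tree, cross


def _owl_restriction(prop: str, forward: bool, filler_expr: str,
                     cc: Optional[CardinalityConstraint]) -> str:
    p = f":{prop}" if forward else f"ObjectInverseOf(:{prop})"
    if cc is None:
        return f"ObjectSomeValuesFrom({p} {filler_expr})"
    if cc.is_exact:
        return f"ObjectExactCardinality({cc.min} {p} {filler_expr})"
    parts = []
    if cc.min:
        parts.append(f"ObjectMinCardinality({cc.min} {p} {filler_expr})")
    if cc.max is not None:
        parts.append(f"ObjectMaxCardinality({cc.max} {p} {filler_expr})")
    if not parts:
        return f"ObjectSomeValuesFrom({p} {filler_expr})"
    return parts[0] if len(parts) == 1 else f"ObjectIntersectionOf({' '.join(parts)})"


def export_owl2_functional(kb: KnowledgeBase) -> tuple[str, LossReport]:
    """Export to OWL2 functional syntax, reporting everything dropped.

    Each rule becomes ``SubClassOf(:Root <nested existential restrictions>)``
    along a breadth-first spanning tree of its graph; cross-edges and Skolem
    equalities have no tree-shaped OWL counterpart and are recorded in the
    returned :class:`LossReport` (equalities are additionally emitted as
    ``rdfs:comment`` annotations so no semantics are silently added).
    """
    out: list[str] = [
        f"Prefix(:=<{_OWL_PREFIX}>)",
        "Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)",
        "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
        "Ontology(<http://example.org/biokr>",
    ]
    data_props = sorted({p for r in kb.iter_rules() for _, p, _ in r.property_assertions})
    for name in sorted(kb.classes):
        out.append(f"Declaration(Class(:{name}))")
    for name in sorted(kb.relations):
        if name in data_props:
            out.append(f"Declaration(DataProperty(:{name}))")
        else:
            out.append(f"Declaration(ObjectProperty(:{name}))")
    for name in sorted(kb.classes):
        for p in sorted(kb.classes[name].parents):
            out.append(f"SubClassOf(:{name} :{p})")
    seen_disjoint: set[tuple[str, str]] = set()
    for name in sorted(kb.classes):
        for d in sorted(kb.classes[name].disjoint_with):
            pair = tuple(sorted((name, d)))
            if pair not in seen_disjoint:
                seen_disjoint.add(pair)
                out.append(f"DisjointClasses(:{pair[0]} :{pair[1]})")
    seen_inverse: set[tuple[str, str]] = set()
    for name in sorted(kb.relations):
        r = kb.relations[name]
        if r.parent:
            out.append(f"SubObjectPropertyOf(:{name} :{r.parent})")
        if r.inverse:
            pair = tuple(sorted((name, r.inverse)))
            if pair not in seen_inverse:
                seen_inverse.add(pair)
                out.append(f"InverseObjectProperties(:{pair[0]} :{pair[1]})")
    for (cls, rel, filler), cc in sorted(kb.constraints.items()):
        out.append(f"SubClassOf(:{cls} {_owl_restriction(rel, True, ':' + filler, cc)})")

    dropped: list[tuple[str, str, str, str]] = []
    non_tree = 0
    eq_dropped = 0
    n_rules = 0
    for rule in kb.iter_rules():
        n_rules += 1
        tree, cross = _spanning_tree(rule)
        if not check_tree_model(rule).is_tree:
            non_tree += 1
        for e in cross:
            dropped.append((rule.rule_id, e.subject, e.relation, e.object))
        children: dict[str, list[tuple[RuleEdge, bool]]] = {}
        for edge, forward in tree:
            parent = edge.subject if forward else edge.object
            children.setdefault(parent, []).append((edge, forward))
        props_by_var: dict[str, list[tuple[str, str]]] = {}
        for var, prop, lit in rule.property_assertions:
            props_by_var.setdefault(var, []).append((prop, lit))

        def expr_for(var: str) -> str:
            node = rule.node(var)
            parts = [f":{node.class_label}"]
            for prop, lit in props_by_var.get(var, []):
                parts.append(f'DataHasValue(:{prop} "{lit}"^^xsd:string)')
            for edge, forward in children.get(var, []):
                child = edge.object if forward else edge.subject
                parts.append(_owl_restriction(edge.relation, forward, expr_for(child), edge.cardinality))
            if len(parts) == 1:
                return parts[0]
            return f"ObjectIntersectionOf({' '.join(parts)})"

        root = rule.root_var
        root_parts = [f'DataHasValue(:{p} "{lit}"^^xsd:string)' for p, lit in props_by_var.get(root, [])]
        root_parts += [
            _owl_restriction(e.relation, fwd, expr_for(e.object if fwd else e.subject), e.cardinality)
            for e, fwd in children.get(root, [])
        ]
        if root_parts:
            sup = root_parts[0] if len(root_parts) == 1 else f"ObjectIntersectionOf({' '.join(root_parts)})"
            out.append(f"SubClassOf(:{rule.root_class} {sup})")
        for eq in rule.equalities:
            eq_dropped += 1
            out.append(
                f'AnnotationAssertion(rdfs:comment :{rule.root_class} '
                f'"skolem-equality {eq.left} == {eq.right} (rule {rule.rule_id})")'
            )
    out.append(")")
    report = LossReport(
        rules_exported=n_rules,
        non_tree_rules=non_tree,
        dropped_edges=tuple(dropped),
        equalities_dropped=eq_dropped,
    )
    return "\n".join(out) + "\n", report


# ---------------------------------------------------------------------------
# First-order export (non-lossy) and its re-parser


def _fn_symbol(term: SkolemTerm) -> str:
    return f"'{term.function_name}@{term.scope}'"


def _fol_term(rule: SkolemizedRule, var: str) -> str:
    if var == rule.root_var:
        return "X"
    return f"{_fn_symbol(rule.term_map[var])}(X)"


def export_fol(kb: KnowledgeBase) -> str:
    """Non-lossy TPTP-style first-order export.

    One ``fof`` per axiom; rules are emitted in Skolemized form (one
    implication whose consequent conjoins class atoms over Skolem terms,
    relation atoms, reified property values and equality atoms). Relation
    metadata and cardinality constraints are reified so that
    :func:`parse_fol` can reconstruct an isomorphic knowledge base.
    """
    lines = ["% biokr first-order export v1"]
    for name in sorted(kb.classes):
        lines.append(f"fof('class:{name}', axiom, class('{name}')).")
    for name in sorted(kb.classes):
        for p in sorted(kb.classes[name].parents):
            lines.append(f"fof('subclass:{name}:{p}', axiom, ! [X] : ('{name}'(X) => '{p}'(X))).")
    seen: set[tuple[str, str]] = set()
    for name in sorted(kb.classes):
        for d in sorted(kb.classes[name].disjoint_with):
            pair = tuple(sorted((name, d)))
            if pair not in seen:
                seen.add(pair)
                lines.append(
                    f"fof('disjoint:{pair[0]}:{pair[1]}', axiom, "
                    f"! [X] : ~('{pair[0]}'(X) & '{pair[1]}'(X)))."
                )
    for name in sorted(kb.relations):
        r = kb.relations[name]
        lines.append(f"fof('relation:{name}', axiom, relation('{name}', '{r.kind.value}')).")
        if r.parent:
            lines.append(
                f"fof('subrelation:{name}:{r.parent}', axiom, "
                f"! [X,Y] : ('{name}'(X,Y) => '{r.parent}'(X,Y)))."
            )
    seen_inv: set[tuple[str, str]] = set()
    for name in sorted(kb.relations):
        r = kb.relations[name]
        if r.inverse:
            pair = tuple(sorted((name, r.inverse)))
            if pair not in seen_inv:
                seen_inv.add(pair)
                lines.append(
                    f"fof('inverse:{pair[0]}:{pair[1]}', axiom, "
                    f"! [X,Y] : ('{pair[0]}'(X,Y) <=> '{pair[1]}'(Y,X)))."
                )
    for (cls, rel, filler), cc in sorted(kb.constraints.items()):
        mx = "inf" if cc.max is None else cc.max
        lines.append(
            f"fof('cardinality:{cls}:{rel}:{filler}', axiom, "
            f"cardinality('{cls}', '{rel}', '{filler}', {cc.min}, {mx}))."
        )
    for rule in kb.iter_rules():
        conj: list[str] = []
        for var, term in rule.terms:
            node = rule.node(var)
            conj.append(f"'{node.class_label}'({_fn_symbol(term)}(X))")
        for e in rule.edges:
            conj.append(f"'{e.relation}'({_fol_term(rule, e.subject)}, {_fol_term(rule, e.object)})")
            if e.cardinality is not None:
                cc = e.cardinality
                mx = "inf" if cc.max is None else cc.max
                # endpoints named canonically (root -> x, existential -> its
                # Skolem function) so parse_fol can re-key them
                term_map = rule.term_map
                s_name = "x" if e.subject == rule.root_var else term_map[e.subject].function_name
                o_name = "x" if e.object == rule.root_var else term_map[e.object].function_name
                lines.append(
                    f"fof('rule-edge-cardinality:{rule.rule_id}:{s_name}:{e.relation}:{o_name}', "
                    f"axiom, rule_edge_cardinality('{rule.rule_id}', '{s_name}', "
                    f"'{e.relation}', '{o_name}', {cc.min}, {mx}))."
                )
        for var, prop, lit in rule.property_assertions:
            conj.append(f"property_value({_fol_term(rule, var)}, '{prop}', '{lit}')")
        for eq in rule.equalities:
            conj.append(f"{_fn_symbol(eq.left)}(X) = {_fn_symbol(eq.right)}(X)")
        body = " & ".join(conj) if conj else "$true"
        lines.append(
            f"fof('rule:{rule.rule_id}:{rule.root_class}', axiom, "
            f"! [X] : ('{rule.root_class}'(X) => ({body})))."
        )
    return "\n".join(lines) + "\n"


_FOF_RE = re.compile(r"^fof\('([^']*)',\s*axiom,\s*(.*)\)\.\s*$")
_ATOM_RE = re.compile(r"'([^']*)'|\b([A-Za-z0-9_]+)\b")


def _split_conjuncts(body: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "&" and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    if cur:
        parts.append("".join(cur).strip())
    return [p for p in parts if p]


_CLASS_ATOM = re.compile(r"^'([^']+)'\((X|'[^']+@[^']+'\(X\))\)$")
_EDGE_ATOM = re.compile(r"^'([^']+)'\((X|'[^']+@[^']+'\(X\)),\s*(X|'[^']+@[^']+'\(X\))\)$")
_PROP_ATOM = re.compile(r"^property_value\((X|'[^']+@[^']+'\(X\)),\s*'([^']+)',\s*'([^']+)'\)$")
_EQ_ATOM = re.compile(r"^'([^']+)@([^']+)'\(X\)\s*=\s*'([^']+)@([^']+)'\(X\)$")
_TERM_RE = re.compile(r"^'([^']+)@([^']+)'\(X\)$")


def parse_fol(text: str) -> KnowledgeBase:
    """Reconstruct a knowledge base from :func:`export_fol` output.

    Accepts exactly the regular fragment that exporter emits (it is not a
    general TPTP reader). The result is isomorphic to the exported KB up to
    rule-variable renaming: existential variables are named after their
    Skolem functions.
    """
    classes: dict[str, dict] = {}
    relations: dict[str, dict] = {}
    constraints: list[tuple[str, str, str, CardinalityConstraint]] = []
    edge_cards: dict[tuple[str, str, str, str], CardinalityConstraint] = {}
    rule_bodies: list[tuple[str, str, str]] = []  # (rule id, root class, body)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        m = _FOF_RE.match(line)
        if m is None:
            raise KBSyntaxError(f"unrecognized line: {line[:60]!r}", lineno)
        name, body = m.group(1), m.group(2)
        kind, *fields = name.split(":")
        if kind == "class":
            classes.setdefault(fields[0], {"parents": set(), "disjoint": set()})
        elif kind == "subclass":
            classes.setdefault(fields[0], {"parents": set(), "disjoint": set()})["parents"].add(fields[1])
        elif kind == "disjoint":
            classes.setdefault(fields[0], {"parents": set(), "disjoint": set()})["disjoint"].add(fields[1])
        elif kind == "relation":
            rm = re.match(r"^relation\('([^']+)',\s*'([^']+)'\)$", body)
            if rm is None:
                raise KBSyntaxError(f"malformed relation axiom: {body!r}", lineno)
            relations.setdefault(rm.group(1), {})["kind"] = RelationKind(rm.group(2))
        elif kind == "subrelation":
            relations.setdefault(fields[0], {})["parent"] = fields[1]
        elif kind == "inverse":
            relations.setdefault(fields[0], {})["inverse"] = fields[1]
            relations.setdefault(fields[1], {})["inverse"] = fields[0]
        elif kind == "cardinality":
            cm = re.match(
                r"^cardinality\('[^']+',\s*'[^']+',\s*'[^']+',\s*(\d+),\s*(\d+|inf)\)$", body
            )
            if cm is None:
                raise KBSyntaxError(f"malformed cardinality axiom: {body!r}", lineno)
            mx = None if cm.group(2) == "inf" else int(cm.group(2))
            constraints.append((fields[0], fields[1], fields[2], CardinalityConstraint(int(cm.group(1)), mx)))
        elif kind == "rule-edge-cardinality":
            cm = re.search(r",\s*(\d+),\s*(\d+|inf)\)$", body)
            if cm is None:
                raise KBSyntaxError(f"malformed rule-edge-cardinality axiom: {body!r}", lineno)
            mx = None if cm.group(2) == "inf" else int(cm.group(2))
            edge_cards[(fields[0], fields[1], fields[2], fields[3])] = CardinalityConstraint(
                int(cm.group(1)), mx
            )
        elif kind == "rule":
            bm = re.match(r"^!\s*\[X\]\s*:\s*\('[^']+'\(X\)\s*=>\s*\((.*)\)\)$", body)
            if bm is None:
                raise KBSyntaxError(f"malformed rule axiom: {body!r}", lineno)
            rule_bodies.append((fields[0], fields[1], bm.group(1)))
        else:
            raise KBSyntaxError(f"unknown axiom name {name!r}", lineno)

    kb = KnowledgeBase()
    kb.add_class([
        ClassDef(n, frozenset(d["parents"]), frozenset(d["disjoint"]))
        for n, d in sorted(classes.items())
    ])
    kb.add_relation([
        RelationDef(n, d.get("kind", RelationKind.STRUCTURAL), d.get("parent"), d.get("inverse"))
        for n, d in sorted(relations.items())
    ])

    def var_of(term_text: str, rule_id: str) -> str:
        if term_text == "X":
            return "x"
        tm = _TERM_RE.match(term_text)
        assert tm is not None
        if tm.group(2) != rule_id:
            raise KBError(f"term {term_text} scoped outside rule {rule_id!r} used as an edge endpoint")
        return tm.group(1)

    srules: dict[str, SkolemizedRule] = {}
    pending_eqs: list[tuple[str, str, str, str, str]] = []
    for rule_id, root_class, body in rule_bodies:
        nodes = [RuleNode("x", root_class, Quantifier.UNIVERSAL_ROOT)]
        terms: list[tuple[str, SkolemTerm]] = []
        edges: list[RuleEdge] = []
        props: list[tuple[str, str, str]] = []
        conjuncts = [] if body.strip() == "$true" else _split_conjuncts(body)
        for atom in conjuncts:
            em = _EQ_ATOM.match(atom)
            if em is not None:
                pending_eqs.append((rule_id, em.group(1), em.group(2), em.group(3), em.group(4)))
                continue
            pm = _PROP_ATOM.match(atom)
            if pm is not None:
                props.append((var_of(pm.group(1), rule_id), pm.group(2), pm.group(3)))
                continue
            edm = _EDGE_ATOM.match(atom)
            if edm is not None:
                s = var_of(edm.group(2), rule_id)
                o = var_of(edm.group(3), rule_id)
                card = edge_cards.get((rule_id, s, edm.group(1), o))
                edges.append(RuleEdge(s, edm.group(1), o, card))
                continue
            cm = _CLASS_ATOM.match(atom)
            if cm is not None and cm.group(2) != "X":
                fn = var_of(cm.group(2), rule_id)
                nodes.append(RuleNode(fn, cm.group(1), Quantifier.EXISTENTIAL))
                terms.append((fn, SkolemTerm(fn, "x", rule_id)))
                continue
            raise KBError(f"rule {rule_id!r}: unrecognized conjunct {atom!r}")
        srules[rule_id] = SkolemizedRule(
            rule_id, root_class, tuple(nodes), tuple(edges), tuple(props), tuple(terms)
        )
    for rule_id in sorted(srules):
        kb.add_rule(srules[rule_id])
    eqs_by_rule: dict[str, list[EqualityStatement]] = {}
    for rule_id, lfn, lscope, rfn, rscope in pending_eqs:
        eqs_by_rule.setdefault(rule_id, []).append(
            EqualityStatement(SkolemTerm(lfn, "x", lscope), SkolemTerm(rfn, "x", rscope))
        )
    for rule_id, eqs in eqs_by_rule.items():
        kb.attach_equalities(rule_id, tuple(eqs))
    for cls, rel, filler, cc in constraints:
        kb.add_constraint(cls, rel, filler, cc)
    return kb


def canonical_rule_form(srule: SkolemizedRule) -> SkolemizedRule:
    """Rename rule variables canonically (root -> ``x``, existentials ->
    their Skolem function names) so rules can be compared up to renaming."""
    mapping = {srule.root_var: "x"}
    for var, term in srule.terms:
        mapping[var] = term.function_name
    nodes = tuple(
        sorted(
            (replace(n, var_id=mapping[n.var_id]) for n in srule.nodes),
            key=lambda n: (n.quantifier is not Quantifier.UNIVERSAL_ROOT, n.var_id),
        )
    )
    edges = tuple(
        sorted(
            (replace(e, subject=mapping[e.subject], object=mapping[e.object]) for e in srule.edges),
            key=lambda e: (e.subject, e.relation, e.object),
        )
    )
    props = tuple(sorted((mapping[v], p, lit) for v, p, lit in srule.property_assertions))
    terms = tuple(sorted(
        (mapping[v], replace(t, argument="x")) for v, t in srule.terms
    ))
    eqs = tuple(sorted(
        (EqualityStatement(replace(eq.left, argument="x"), replace(eq.right, argument="x"))
         for eq in srule.equalities),
        key=lambda eq: (str(eq.left), str(eq.right)),
    ))
    return SkolemizedRule(srule.rule_id, srule.root_class, nodes, edges, props, terms, eqs)


def kb_isomorphic(a: KnowledgeBase, b: KnowledgeBase) -> bool:
    """Structural equality up to rule-variable renaming.

    Disjointness is compared as a symmetric pair set: which of the two
    classes carries the declaration is presentation, not content (the FOL
    export normalizes it to the lexicographically first class).
    """

    def shape(kb: KnowledgeBase):
        classes = {n: frozenset(c.parents) for n, c in kb.classes.items()}
        disjoint = {
            tuple(sorted((n, d)))
            for n, c in kb.classes.items()
            for d in c.disjoint_with
        }
        return classes, disjoint

    if (shape(a) != shape(b)
            or sorted(a.relations.items()) != sorted(b.relations.items())
            or sorted(a.constraints.items()) != sorted(b.constraints.items())):
        return False
    ra = {r.rule_id: canonical_rule_form(r) for r in a.iter_rules()}
    rb = {r.rule_id: canonical_rule_form(r) for r in b.iter_rules()}
    return ra == rb
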