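"""Core data model for frame-style knowledge bases.

A knowledge base couples a class taxonomy and a relation hierarchy with
*graph-structured existential rules*: each rule describes every instance of a
root class by a graph of typed variables, where the root variable is
universally quantified and all other variables are existentially quantified.
Rules are stored Skolemized -- every existential variable is replaced by a
function term over the root variable -- so that rules of different classes can
refer to each other's fillers through explicit equality statements, the
mechanism by which a subclass specializes an inherited filler instead of
duplicating it.

Rule graphs need not be trees: a variable may have two or more predecessors
(e.g. a chromosome that is both a part of a cell and inside its nucleus).
:func:`check_tree_model` diagnoses exactly this, which is what makes the OWL2
translation of such rules lossy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Literal, Optional, Union

__all__ = [
    "KBError",
    "ConsistencyError",
    "RelationKind",
    "Quantifier",
    "ClassDef",
    "RelationDef",
    "CardinalityConstraint",
    "RuleNode",
    "RuleEdge",
    "GraphRule",
    "SkolemTerm",
    "EqualityStatement",
    "SkolemizedRule",
    "TreeReport",
    "KnowledgeBase",
    "Individual",
    "InstanceGraph",
    "Conflict",
    "skolemize",
    "deskolemize",
    "check_tree_model",
    "check_consistency",
    "skolem_function_names",
]

_IDENT_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9-]*$")


class KBError(ValueError):
    """Raised on violations of knowledge-base invariants."""


class ConsistencyError(KBError):
    """Raised when an operation would merge individuals of disjoint classes."""


def _check_ident(name: str, what: str = "identifier") -> str:
    if not _IDENT_RE.match(name):
        raise KBError(f"invalid {what} {name!r}: must match [A-Za-z0-9-]+ and not start with '-'")
    if "--" in name:
        raise KBError(f"invalid {what} {name!r}: double hyphen not allowed")
    return name


class RelationKind(str, Enum):
    PARTICIPANT = "participant"
    STRUCTURAL = "structural"
    SPATIAL = "spatial"
    FUNCTIONAL = "functional"
    PROPERTY = "property"
    TAXONOMY_INTERNAL = "taxonomy-internal"


class Quantifier(str, Enum):
    UNIVERSAL_ROOT = "universal-root"
    EXISTENTIAL = "existential"


@dataclass(frozen=True)
class ClassDef:
    """A named class with its direct superclasses and declared disjointness."""

    name: str
    parents: frozenset[str] = frozenset()
    disjoint_with: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        _check_ident(self.name, "class name")
        object.__setattr__(self, "parents", frozenset(self.parents))
        object.__setattr__(self, "disjoint_with", frozenset(self.disjoint_with))


@dataclass(frozen=True)
class RelationDef:
    """A binary relation, optionally placed in a relation hierarchy.

    ``inverse`` is symmetric: if r.inverse == s then s.inverse == r must hold
    in the same knowledge base.
    """

    name: str
    kind: RelationKind = RelationKind.STRUCTURAL
    parent: Optional[str] = None
    inverse: Optional[str] = None

    def __post_init__(self) -> None:
        _check_ident(self.name, "relation name")
        object.__setattr__(self, "kind", RelationKind(self.kind))


@dataclass(frozen=True)
class CardinalityConstraint:
    """``min..max`` filler count; ``max=None`` means unbounded.

    ``exactly n`` is min == max == n; ``exactly 0`` is the standard encoding
    of negative information (the filler never occurs).
    """

    min: int
    max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min < 0:
            raise KBError(f"cardinality min must be nonnegative, got {self.min}")
        if self.max is not None and self.max < self.min:
            raise KBError(f"cardinality min {self.min} exceeds max {self.max}")

    @classmethod
    def exactly(cls, n: int) -> "CardinalityConstraint":
        return cls(n, n)

    @property
    def is_exact(self) -> bool:
        return self.max is not None and self.min == self.max

    def __str__(self) -> str:
        if self.is_exact:
            return f"exactly {self.min}"
        return f"{self.min}..{'*' if self.max is None else self.max}"


@dataclass(frozen=True)
class RuleNode:
    var_id: str
    class_label: str
    quantifier: Quantifier = Quantifier.EXISTENTIAL

    def __post_init__(self) -> None:
        _check_ident(self.var_id, "variable")
        object.__setattr__(self, "quantifier", Quantifier(self.quantifier))


@dataclass(frozen=True)
class RuleEdge:
    """Directed edge ``relation(subject, object)`` between rule variables."""

    subject: str
    relation: str
    object: str
    cardinality: Optional[CardinalityConstraint] = None


@dataclass(frozen=True)
class SkolemTerm:
    """A function term over a rule's universal root variable.

    ``scope`` is the identifier of the rule that introduced the function;
    function names are fresh per rule, so (scope, function_name) is globally
    unique within a knowledge base.
    """

    function_name: str
    argument: str = "x"
    scope: str = ""

    def __str__(self) -> str:
        if self.scope:
            return f"{self.function_name}@{self.scope}({self.argument})"
        return f"{self.function_name}({self.argument})"


@dataclass(frozen=True)
class EqualityStatement:
    """Declares two Skolem terms co-referent for every shared root instance."""

    left: SkolemTerm
    right: SkolemTerm


@dataclass(frozen=True)
class GraphRule:
    """An existentially quantified, possibly non-tree class description."""

    rule_id: str
    root_class: str
    nodes: tuple[RuleNode, ...]
    edges: tuple[RuleEdge, ...] = ()
    property_assertions: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        _check_ident(self.rule_id, "rule id")
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "property_assertions", tuple(tuple(p) for p in self.property_assertions))

    @property
    def root_var(self) -> str:
        for n in self.nodes:
            if n.quantifier is Quantifier.UNIVERSAL_ROOT:
                return n.var_id
        raise KBError(f"rule {self.rule_id}: no universal-root node")

    def node(self, var_id: str) -> RuleNode:
        for n in self.nodes:
            if n.var_id == var_id:
                return n
        raise KBError(f"rule {self.rule_id}: no node {var_id!r}")


@dataclass(frozen=True)
class SkolemizedRule:
    """A :class:`GraphRule` with existential variables bound to Skolem terms.

    ``nodes``/``edges`` are kept over the original variable ids; ``terms``
    maps each existential variable to its Skolem term, so the rewritten form
    (edges over function terms) is recoverable without losing the graph.
    """

    rule_id: str
    root_class: str
    nodes: tuple[RuleNode, ...]
    edges: tuple[RuleEdge, ...]
    property_assertions: tuple[tuple[str, str, str], ...]
    terms: tuple[tuple[str, SkolemTerm], ...]  # (var_id, term), declaration order
    equalities: tuple[EqualityStatement, ...] = ()

    @property
    def root_var(self) -> str:
        for n in self.nodes:
            if n.quantifier is Quantifier.UNIVERSAL_ROOT:
                return n.var_id
        raise KBError(f"rule {self.rule_id}: no universal-root node")

    @property
    def term_map(self) -> dict[str, SkolemTerm]:
        return dict(self.terms)

    def node(self, var_id: str) -> RuleNode:
        for n in self.nodes:
            if n.var_id == var_id:
                return n
        raise KBError(f"rule {self.rule_id}: no node {var_id!r}")

    def term_for_function(self, function_name: str) -> SkolemTerm:
        for _, t in self.terms:
            if t.function_name == function_name:
                return t
        raise KBError(f"rule {self.rule_id}: no Skolem function {function_name!r}")


@dataclass(frozen=True)
class TreeReport:
    """Outcome of the tree-model check on a rule graph."""

    is_tree: bool
    offending_nodes: tuple[tuple[str, int], ...]  # (var_id, distinct predecessor count)


@dataclass(frozen=True)
class Conflict:
    kind: Literal["disjoint-labels", "cardinality"]
    individual: str
    detail: str

    def __str__(self) -> str:
        return f"{self.kind}: {self.individual}: {self.detail}"


# ---------------------------------------------------------------------------
# Knowledge base


class KnowledgeBase:
    """Classes, relations, Skolemized rules and cardinality constraints.

    All mutators validate referential integrity and acyclicity before
    committing, so a constructed instance always satisfies its invariants.
    """

    def __init__(self) -> None:
        self.classes: dict[str, ClassDef] = {}
        self.relations: dict[str, RelationDef] = {}
        self.rules: dict[str, list[SkolemizedRule]] = {}
        self.constraints: dict[tuple[str, str, str], CardinalityConstraint] = {}

    # -- taxonomy ----------------------------------------------------------

    def superclasses(self, name: str, *, reflexive: bool = False) -> set[str]:
        """Transitive superclass closure of ``name``."""
        if name not in self.classes:
            raise KBError(f"unknown class {name!r}")
        seen: set[str] = {name} if reflexive else set()
        stack = list(self.classes[name].parents)
        while stack:
            p = stack.pop()
            if p not in seen:
                seen.add(p)
                stack.extend(self.classes[p].parents)
        if not reflexive:
            seen.discard(name)
        return seen

    def subclasses(self, name: str, *, reflexive: bool = False) -> set[str]:
        if name not in self.classes:
            raise KBError(f"unknown class {name!r}")
        out = {c for c in self.classes if name in self.superclasses(c)}
        if reflexive:
            out.add(name)
        else:
            out.discard(name)
        return out

    def is_subclass_of(self, sub: str, sup: str) -> bool:
        """Reflexive-transitive subclass test."""
        return sub == sup or sup in self.superclasses(sub)

    def comparable(self, a: str, b: str) -> bool:
        return self.is_subclass_of(a, b) or self.is_subclass_of(b, a)

    def disjoint(self, a: str, b: str) -> bool:
        """Disjointness, inherited downward through the taxonomy."""
        ups_a = self.superclasses(a, reflexive=True)
        ups_b = self.superclasses(b, reflexive=True)
        for ca in ups_a:
            decl = self.classes[ca].disjoint_with
            if decl & ups_b:
                return True
        for cb in ups_b:
            if self.classes[cb].disjoint_with & ups_a:
                return True
        return False

    def common_ancestors(self, a: str, b: str) -> set[str]:
        return self.superclasses(a, reflexive=True) & self.superclasses(b, reflexive=True)

    def class_depth(self, name: str) -> int:
        """Longest parent chain above ``name`` (top-level classes have depth 0)."""
        parents = self.classes[name].parents
        if not parents:
            return 0
        return 1 + max(self.class_depth(p) for p in parents)

    def deepest_common_ancestor(self, a: str, b: str) -> Optional[str]:
        common = self.common_ancestors(a, b)
        if not common:
            return None
        return max(sorted(common), key=lambda c: (self.class_depth(c), c))

    # -- relation hierarchy ------------------------------------------------

    def subrelations(self, name: str) -> set[str]:
        """Reflexive-transitive sub-relation closure."""
        if name not in self.relations:
            raise KBError(f"unknown relation {name!r}")
        out = {name}
        changed = True
        while changed:
            changed = False
            for r in self.relations.values():
                if r.parent in out and r.name not in out:
                    out.add(r.name)
                    changed = True
        return out

    def direct_subrelations(self, name: str) -> set[str]:
        if name not in self.relations:
            raise KBError(f"unknown relation {name!r}")
        return {r.name for r in self.relations.values() if r.parent == name}

    def superrelations(self, name: str) -> set[str]:
        if name not in self.relations:
            raise KBError(f"unknown relation {name!r}")
        out = {name}
        cur = self.relations[name].parent
        while cur is not None and cur not in out:
            out.add(cur)
            cur = self.relations[cur].parent
        return out

    # -- mutators ----------------------------------------------------------

    def add_class(self, cls: Union[ClassDef, Iterable[ClassDef]]) -> "KnowledgeBase":
        """Add one class (or a batch; batches may reference each other)."""
        batch = [cls] if isinstance(cls, ClassDef) else list(cls)
        staged = dict(self.classes)
        for c in batch:
            if c.name in staged:
                raise KBError(f"duplicate class {c.name!r}")
            staged[c.name] = c
        for c in batch:
            for p in c.parents:
                if p not in staged:
                    raise KBError(f"class {c.name!r}: unknown parent {p!r}")
            for d in c.disjoint_with:
                if d not in staged:
                    raise KBError(f"class {c.name!r}: unknown disjoint class {d!r}")
        _check_taxonomy_acyclic(staged)
        _check_disjointness_sane(staged)
        self.classes = staged
        return self

    def add_relation(self, rel: Union[RelationDef, Iterable[RelationDef]]) -> "KnowledgeBase":
        batch = [rel] if isinstance(rel, RelationDef) else list(rel)
        staged = dict(self.relations)
        for r in batch:
            if r.name in staged:
                raise KBError(f"duplicate relation {r.name!r}")
            staged[r.name] = r
        for r in batch:
            if r.parent is not None and r.parent not in staged:
                raise KBError(f"relation {r.name!r}: unknown parent {r.parent!r}")
            if r.inverse is not None:
                inv = staged.get(r.inverse)
                if inv is None:
                    raise KBError(f"relation {r.name!r}: unknown inverse {r.inverse!r}")
                if inv.inverse is None:
                    # one-sided declaration: symmetrize
                    staged[inv.name] = replace(inv, inverse=r.name)
                elif inv.inverse != r.name:
                    raise KBError(
                        f"inverse must be symmetric: {r.name!r} names {r.inverse!r} "
                        f"but {r.inverse!r} names {inv.inverse!r}"
                    )
        _check_relation_hierarchy_acyclic(staged)
        self.relations = staged
        return self

    def add_rule(self, rule: Union[GraphRule, SkolemizedRule]) -> "KnowledgeBase":
        """Add a rule (GraphRules are Skolemized on entry)."""
        srule = skolemize(rule) if isinstance(rule, GraphRule) else rule
        problems = self.validate_rule(srule)
        if problems:
            raise KBError(f"invalid rule {srule.rule_id!r}: " + "; ".join(problems))
        if any(srule.rule_id == r.rule_id for rs in self.rules.values() for r in rs):
            raise KBError(f"duplicate rule id {srule.rule_id!r}")
        self._validate_equalities(srule)
        self.rules.setdefault(srule.root_class, []).append(srule)
        return self

    def add_constraint(
        self, cls: str, relation: str, filler: str, constraint: CardinalityConstraint
    ) -> "KnowledgeBase":
        for name, what in ((cls, "class"), (filler, "class")):
            if name not in self.classes:
                raise KBError(f"constraint references unknown {what} {name!r}")
        if relation not in self.relations:
            raise KBError(f"constraint references unknown relation {relation!r}")
        self.constraints[(cls, relation, filler)] = constraint
        return self

    # -- validation --------------------------------------------------------

    def validate_rule(self, rule: Union[GraphRule, SkolemizedRule]) -> list[str]:
        """Return all invariant violations of ``rule`` against this KB.

        An empty list means the rule is valid. Violations are returned, not
        raised, so callers can collect diagnostics over a whole document.
        """
        problems: list[str] = []
        if self.classes.get(rule.root_class) is None:
            problems.append(f"unknown root class {rule.root_class!r}")
        roots = [n for n in rule.nodes if n.quantifier is Quantifier.UNIVERSAL_ROOT]
        if len(roots) != 1:
            problems.append(f"expected exactly one universal-root node, found {len(roots)}")
        elif roots[0].class_label != rule.root_class:
            problems.append(
                f"root node class {roots[0].class_label!r} differs from root_class {rule.root_class!r}"
            )
        var_ids = [n.var_id for n in rule.nodes]
        if len(set(var_ids)) != len(var_ids):
            problems.append("duplicate variable ids")
        vars_set = set(var_ids)
        for n in rule.nodes:
            if n.class_label not in self.classes:
                problems.append(f"node {n.var_id!r}: unknown class {n.class_label!r}")
        seen_edges: set[tuple[str, str, str]] = set()
        for e in rule.edges:
            if e.subject not in vars_set or e.object not in vars_set:
                problems.append(f"edge {e.relation}({e.subject},{e.object}): endpoint not a rule node")
            if e.relation not in self.relations:
                problems.append(f"edge references undeclared relation {e.relation!r}")
            triple = (e.subject, e.relation, e.object)
            if triple in seen_edges:
                problems.append(f"duplicate edge {e.relation}({e.subject},{e.object})")
            seen_edges.add(triple)
        for var, prop, _lit in rule.property_assertions:
            if var not in vars_set:
                problems.append(f"property assertion on unknown variable {var!r}")
            if prop not in self.relations:
                problems.append(f"property assertion uses undeclared relation {prop!r}")
        if len(rule.nodes) > 1 and not problems:
            if not _connected_undirected(vars_set, rule.edges):
                problems.append("rule graph is not connected")
        return problems

    def _validate_equalities(self, srule: SkolemizedRule) -> None:
        lineage = self.superclasses(srule.root_class, reflexive=True) | self.subclasses(srule.root_class)
        own_functions = {t.function_name for _, t in srule.terms}
        for eq in srule.equalities:
            for side, term in (("left", eq.left), ("right", eq.right)):
                if term.scope == srule.rule_id:
                    if term.function_name not in own_functions:
                        raise KBError(
                            f"rule {srule.rule_id!r}: equality {side} term {term} not declared in rule"
                        )
                    continue
                other = self.rule_by_id(term.scope)
                if other is None:
                    raise KBError(f"rule {srule.rule_id!r}: equality references unknown rule {term.scope!r}")
                if other.root_class not in lineage:
                    raise KBError(
                        f"rule {srule.rule_id!r}: equality links to rule {term.scope!r} of class "
                        f"{other.root_class!r}, outside the subclass lineage of {srule.root_class!r}"
                    )
                other.term_for_function(term.function_name)  # raises if absent

    def attach_equalities(
        self, rule_id: str, equalities: tuple[EqualityStatement, ...]
    ) -> "KnowledgeBase":
        """Replace the stored rule's equality statements (validated).

        Used by loaders: rules are installed first, then equalities attached,
        so an equality may reference any rule in the document regardless of
        declaration order.
        """
        srule = self.rule_by_id(rule_id)
        if srule is None:
            raise KBError(f"unknown rule {rule_id!r}")
        updated = replace(srule, equalities=tuple(equalities))
        self._validate_equalities(updated)
        rules = self.rules[srule.root_class]
        self.rules[srule.root_class] = [updated if r.rule_id == rule_id else r for r in rules]
        return self

    # -- lookups -----------------------------------------------------------

    def rule_by_id(self, rule_id: str) -> Optional[SkolemizedRule]:
        for rs in self.rules.values():
            for r in rs:
                if r.rule_id == rule_id:
                    return r
        return None

    def rules_for(self, cls: str, *, inherited: bool = True) -> list[SkolemizedRule]:
        """Rules rooted at ``cls`` (and at its superclasses when inherited)."""
        classes = self.superclasses(cls, reflexive=True) if inherited else {cls}
        out: list[SkolemizedRule] = []
        for c in sorted(classes):
            out.extend(self.rules.get(c, []))
        return sorted(out, key=lambda r: r.rule_id)

    def iter_rules(self) -> Iterator[SkolemizedRule]:
        for c in sorted(self.rules):
            yield from sorted(self.rules[c], key=lambda r: r.rule_id)

    def merge(self, other: "KnowledgeBase") -> "KnowledgeBase":
        """Merge ``other`` into self; identical redeclarations are tolerated."""
        for name, c in other.classes.items():
            if name in self.classes:
                if self.classes[name] != c:
                    raise KBError(f"conflicting redeclaration of class {name!r}")
            else:
                self.add_class(c)
        for name, r in other.relations.items():
            if name in self.relations:
                if self.relations[name] != r:
                    raise KBError(f"conflicting redeclaration of relation {name!r}")
            else:
                self.relations[name] = r  # validated in source KB
        added = []
        for rule in other.iter_rules():
            if self.rule_by_id(rule.rule_id) is None:
                self.add_rule(replace(rule, equalities=()))
                added.append(rule)
        for rule in added:
            if rule.equalities:
                self.attach_equalities(rule.rule_id, rule.equalities)
        for key, cc in other.constraints.items():
            self.constraints[key] = cc
        return self

    # -- equality ----------------------------------------------------------

    def _canonical(self) -> tuple:
        return (
            tuple(sorted(self.classes.items())),
            tuple(sorted(self.relations.items())),
            tuple((c, tuple(sorted(rs, key=lambda r: r.rule_id))) for c, rs in sorted(self.rules.items())),
            tuple(sorted(self.constraints.items())),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __repr__(self) -> str:
        n_rules = sum(len(v) for v in self.rules.values())
        return (
            f"<KnowledgeBase: {len(self.classes)} classes, {len(self.relations)} relations, "
            f"{n_rules} rules, {len(self.constraints)} constraints>"
        )


def _check_taxonomy_acyclic(classes: dict[str, ClassDef]) -> None:
    state: dict[str, int] = {}

    def visit(name: str, trail: list[str]) -> None:
        st = state.get(name, 0)
        if st == 2:
            return
        if st == 1:
            raise KBError(f"class taxonomy cycle through {name!r}: {' -> '.join(trail + [name])}")
        state[name] = 1
        for p in classes[name].parents:
            visit(p, trail + [name])
        state[name] = 2

    for n in classes:
        visit(n, [])


def _check_disjointness_sane(classes: dict[str, ClassDef]) -> None:
    def ancestors(name: str) -> set[str]:
        out: set[str] = set()
        stack = list(classes[name].parents)
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(classes[p].parents)
        return out

    for c in classes.values():
        if c.name in c.disjoint_with:
            raise KBError(f"class {c.name!r} declared disjoint with itself")
        ups = ancestors(c.name)
        for d in c.disjoint_with:
            if d in ups or c.name in ancestors(d):
                raise KBError(f"class {c.name!r} disjoint with its ancestor/descendant {d!r}")


def _check_relation_hierarchy_acyclic(relations: dict[str, RelationDef]) -> None:
    for name in relations:
        seen = {name}
        cur = relations[name].parent
        while cur is not None:
            if cur in seen:
                raise KBError(f"relation hierarchy cycle through {name!r}")
            seen.add(cur)
            cur = relations[cur].parent


def _connected_undirected(vars_set: set[str], edges: tuple[RuleEdge, ...]) -> bool:
    if not vars_set:
        return True
    adj: dict[str, set[str]] = {v: set() for v in vars_set}
    for e in edges:
        adj[e.subject].add(e.object)
        adj[e.object].add(e.subject)
    start = next(iter(sorted(vars_set)))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen == vars_set


# ---------------------------------------------------------------------------
# Skolemization


def skolem_function_names(rule: GraphRule) -> dict[str, str]:
    """Deterministic Skolem function names for a rule's existential nodes.

    Kebab-cased ``<node-class>-of`` with an ordinal suffix on collision
    (``ribosome-of``, ``ribosome-of-2``), assigned in node declaration order.
    """
    names: dict[str, str] = {}
    used: dict[str, int] = {}
    for n in rule.nodes:
        if n.quantifier is Quantifier.UNIVERSAL_ROOT:
            continue
        base = f"{n.class_label.lower()}-of"
        count = used.get(base, 0) + 1
        used[base] = count
        names[n.var_id] = base if count == 1 else f"{base}-{count}"
    return names


def skolemize(
    rule: GraphRule, equalities: tuple[EqualityStatement, ...] = ()
) -> SkolemizedRule:
    """Replace each existential node with a Skolem function term over the root.

    Pure and deterministic: re-skolemizing the same rule yields identical
    terms. Declared ``equalities`` (e.g. linking an inherited filler to a
    superclass rule's term) are carried through unchanged.
    """
    root = rule.root_var  # raises if absent
    names = skolem_function_names(rule)
    terms = tuple(
        (n.var_id, SkolemTerm(names[n.var_id], argument=root, scope=rule.rule_id))
        for n in rule.nodes
        if n.quantifier is not Quantifier.UNIVERSAL_ROOT
    )
    return SkolemizedRule(
        rule_id=rule.rule_id,
        root_class=rule.root_class,
        nodes=rule.nodes,
        edges=rule.edges,
        property_assertions=rule.property_assertions,
        terms=terms,
        equalities=tuple(equalities),
    )


def deskolemize(srule: SkolemizedRule) -> GraphRule:
    """Inverse of :func:`skolemize`: Skolem terms back to existential nodes.

    Equality statements are dropped (they have no counterpart in the purely
    existential form); the result is isomorphic to the original rule.
    """
    return GraphRule(
        rule_id=srule.rule_id,
        root_class=srule.root_class,
        nodes=srule.nodes,
        edges=srule.edges,
        property_assertions=srule.property_assertions,
    )


# ---------------------------------------------------------------------------
# Tree-model check


def check_tree_model(rule: Union[GraphRule, SkolemizedRule]) -> TreeReport:
    """Diagnose tree-model violations of a rule's variable graph.

    Builds the directed graph with one node per rule variable and one edge
    from the first to the second argument of every binary predicate, then
    reports every node with two or more distinct incoming edges (parallel
    edges through different relations count separately; a repetition of the
    identical predicate does not). The universal root is additionally
    offending if it has any incoming edge at all: in a rooted tree model the
    root is where the description starts, so an edge back into it (e.g. a
    part that is ``is-part-of`` the root) already breaks the tree shape. A
    rule with an offending node cannot be captured by tree-shaped
    (description-logic) class expressions, which is what makes the OWL2
    export of the rule lossy.

    For a connected rule graph, offending nodes are absent exactly when the
    distinct-edge count equals node count minus one, i.e. when the OWL2
    export drops no edges.
    """
    incoming: dict[str, set[tuple[str, str]]] = {n.var_id: set() for n in rule.nodes}
    for e in rule.edges:
        incoming[e.object].add((e.subject, e.relation))
    root = rule.root_var
    offending = tuple(
        (v, len(es))
        for v, es in sorted(incoming.items())
        if len(es) >= 2 or (v == root and len(es) >= 1)
    )
    return TreeReport(is_tree=not offending, offending_nodes=offending)


# ---------------------------------------------------------------------------
# Instance graphs and consistency


@dataclass
class Individual:
    """A (possibly merged) sample individual in an elaborated graph."""

    id: str
    origin: Union[SkolemTerm, Literal["seed"]]
    class_labels: set[str] = field(default_factory=set)

    def most_specific_labels(self, kb: KnowledgeBase) -> set[str]:
        labels = set(self.class_labels)
        return {
            c for c in labels
            if not any(o != c and kb.is_subclass_of(o, c) for o in labels)
        }


@dataclass
class InstanceGraph:
    """Individuals plus relation triples with per-triple provenance."""

    individuals: dict[str, Individual] = field(default_factory=dict)
    triples: set[tuple[str, str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str, str], str] = field(default_factory=dict)
    property_values: set[tuple[str, str, str]] = field(default_factory=set)

    def add_triple(self, s: str, r: str, o: str, provenance: str) -> None:
        t = (s, r, o)
        if t not in self.triples:
            self.triples.add(t)
            self.provenance[t] = provenance

    def outgoing(self, ind_id: str, relations: Optional[set[str]] = None) -> list[tuple[str, str, str]]:
        return sorted(
            t for t in self.triples
            if t[0] == ind_id and (relations is None or t[1] in relations)
        )

    def instances_of(self, kb: KnowledgeBase, cls: str) -> list[Individual]:
        return sorted(
            (i for i in self.individuals.values()
             if any(kb.is_subclass_of(lbl, cls) for lbl in i.class_labels)),
            key=lambda i: i.id,
        )

    def close_inverses(self, kb: KnowledgeBase) -> None:
        """Add the inverse triple for every triple whose relation has one."""
        for s, r, o in sorted(self.triples):
            inv = kb.relations[r].inverse if r in kb.relations else None
            if inv is not None:
                self.add_triple(o, inv, s, "inverse")


def check_consistency(kb: KnowledgeBase, graph: InstanceGraph) -> list[Conflict]:
    """Report disjointness violations and exceeded exact-cardinality bounds.

    Under open-world reading an elaborated graph may *under*-fill an exact
    constraint without contradiction, so only counts exceeding ``max`` are
    conflicts; disjointness conflicts are individuals whose labels include two
    classes that are (or inherit being) disjoint.
    """
    conflicts: list[Conflict] = []
    for ind in sorted(graph.individuals.values(), key=lambda i: i.id):
        labels = sorted(ind.class_labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if kb.disjoint(a, b):
                    conflicts.append(Conflict("disjoint-labels", ind.id, f"{a} vs {b}"))
    for (cls, rel, filler), cc in sorted(kb.constraints.items()):
        if cc.max is None:
            continue
        for ind in graph.instances_of(kb, cls):
            fillers = {
                o for (s, r, o) in graph.triples
                if s == ind.id and r == rel
                and any(kb.is_subclass_of(lbl, filler) for lbl in graph.individuals[o].class_labels)
            }
            if len(fillers) > cc.max:
                conflicts.append(
                    Conflict(
                        "cardinality", ind.id,
                        f"{rel} {filler}: {len(fillers)} fillers exceed {cc}",
                    )
                )
    return conflicts
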