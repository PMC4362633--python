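"""Bundled knowledge bases: the mini upper ontology and the worked examples.

Every domain fixture is loaded *merged over* the upper ontology, so each one
references only relations the upper ontology declares. The ``plant-cell``
fixture additionally layers over ``cell-a1-a4`` (its classes specialize the
cell taxonomy).
"""

from __future__ import annotations

from importlib import resources

from .io_formats import parse_kb
from .kb_core import KBError, KnowledgeBase

__all__ = ["FIXTURE_NAMES", "load_upper_ontology", "load_example_kb", "fixture_text"]

#: Layering of fixture files: name -> list of data files, applied in order.
_LAYERS: dict[str, tuple[str, ...]] = {
    "upper-ontology": ("upper-ontology.kb",),
    "cell-a1-a4": ("upper-ontology.kb", "cell-a1-a4.kb"),
    "biomembrane": ("upper-ontology.kb", "biomembrane.kb"),
    "plant-cell": ("upper-ontology.kb", "cell-a1-a4.kb", "plant-cell.kb"),
    "dna-gene": ("upper-ontology.kb", "dna-gene.kb"),
}

FIXTURE_NAMES: tuple[str, ...] = tuple(_LAYERS)


def fixture_text(filename: str) -> str:
    """Raw native-dialect text of one bundled data file."""
    return (resources.files("biokr") / "data" / filename).read_text(encoding="utf-8")


def load_upper_ontology() -> KnowledgeBase:
    """The CLIB-style upper layer: Entity / Event / Relation / Role, the
    action vocabulary, participant roles, structural and spatial relations."""
    return load_example_kb("upper-ontology")


def load_example_kb(name: str) -> KnowledgeBase:
    """Load a bundled knowledge base by name, merged over the upper ontology.

    Known names: ``upper-ontology``, ``cell-a1-a4``, ``biomembrane``,
    ``plant-cell``, ``dna-gene``.
    """
    if name not in _LAYERS:
        raise KBError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    kb: KnowledgeBase | None = None
    for filename in _LAYERS[name]:
        kb = parse_kb(fixture_text(filename), base=kb)
    assert kb is not None
    return kb
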