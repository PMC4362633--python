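; Mini CLIB-style upper ontology.
; Four top-level distinctions: things that are (Entity), things that happen
; (Event), associations between things (Relation), and ways entities
; participate in events (Role). The Action subtree is a documented subset of
; the full component library's action vocabulary, covering every action the
; bundled domain fixtures use.

class Entity
class Event
class Relation
class Role

class Action is-a Event
class Attach is-a Action
class Impair is-a Action
class Damage is-a Impair
class Break is-a Damage
class Move is-a Action
class Move-Through is-a Move
class Block is-a Action
class Support is-a Action
class Create is-a Action
class Synthesis is-a Create

class Spatial-Entity is-a Entity

; Participant (case-role) relations: how entities take part in an event.
; Each is a predicate over (event, entity).
relation participant kind participant
relation agent kind participant parent participant
relation object kind participant parent participant
relation instrument kind participant parent participant
relation raw-material kind participant parent participant
relation result kind participant parent participant
relation source kind participant parent participant
relation destination kind participant parent participant
relation site kind participant parent participant

; Structural relations. has-structure has exactly four direct sub-relations;
; element is structural vocabulary but not part of the has-structure bundle.
relation has-structure kind structural
relation has-part kind structural parent has-structure
relation is-part-of kind structural inverse has-part
relation has-region kind structural parent has-structure
relation is-region-of kind structural inverse has-region
relation material kind structural parent has-structure
relation possesses kind structural parent has-structure
relation element kind structural

; Spatial relations.
relation is-inside kind spatial
relation contains kind spatial inverse is-inside

; Functional and event-structure relations.
relation has-function kind functional
relation facilitates kind functional
relation subevent kind functional

; Property relations take literal values or chemical-entity fillers.
relation intensity kind property
relation solubility-in-water kind property
relation permeable-to kind property
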