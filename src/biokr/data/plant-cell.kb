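; Plant cell, cell wall and protoplast.
;
; Every plant cell is the agent of a cell-wall synthesis whose result is a
; cell wall that is part of the plant cell itself; the cell wall's function
; is to support the plant cell, with strong intensity. A protoplast is a
; cell (not a plant cell) without a cell wall: making Protoplast a subclass
; of Plant-Cell would wrongly inherit the cell wall, so it is a subclass of
; Cell, and the missing wall is expressible as an exactly-0 part constraint.
; This fixture layers over the cell knowledge base.

class Plant-Cell is-a Eukaryotic-Cell
class Protoplast is-a Cell
class Cell-Wall is-a Entity
class Synthesis-of-Cell-Wall is-a Synthesis

; The result edge back into the root gives the root an incoming edge: the
; rule graph is not a tree.
rule cell-wall-synthesis of Plant-Cell
  node x Plant-Cell root
  node e Synthesis-of-Cell-Wall
  node w Cell-Wall
  edge e agent x
  edge e result w
  edge w is-part-of x
end

rule cell-wall-support of Plant-Cell
  node x Plant-Cell root
  node w Cell-Wall
  node s Support
  edge x has-part w
  edge w has-function s
  edge s object x
  prop s intensity strong
end

constraint Protoplast has-part Cell-Wall exactly 0
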