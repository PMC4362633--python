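; Worked cell knowledge base.
; Every cell has a ribosome and a chromosome as its parts; every eukaryotic
; cell has a ribosome, a nucleus and a eukaryotic chromosome such that the
; chromosome is inside the nucleus. The chromosome filler inherited from
; Cell is specialized (not duplicated) by the equality statement linking the
; two rules' Skolem terms.

class Cell is-a Entity
class Eukaryotic-Cell is-a Cell
class Ribosome is-a Entity
class Chromosome is-a Entity
class Eukaryotic-Chromosome is-a Chromosome
class Nucleus is-a Entity

rule cell-parts of Cell
  node x Cell root
  node y1 Ribosome
  node y2 Chromosome
  edge x has-part y1
  edge x has-part y2
end

; The nucleus-to-chromosome containment edge gives the chromosome node two
; incoming edges (from the root and from the nucleus): the rule graph is not
; a tree.
rule eukaryotic-cell-parts of Eukaryotic-Cell
  node x Eukaryotic-Cell root
  node y1 Ribosome
  node y2 Nucleus
  node y3 Eukaryotic-Chromosome
  edge x has-part y1
  edge x has-part y2
  edge x has-part y3
  edge y2 contains y3
  equal y3 = cell-parts.chromosome-of
end
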