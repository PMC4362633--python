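; Minimal part-chain knowledge base for relationship-path queries:
; a DNA molecule has a DNA strand as its part, which in turn has a gene as
; its part.

class DNA-Molecule is-a Entity
class DNA-Strand is-a Entity
class Gene is-a Entity

rule dna-molecule-parts of DNA-Molecule
  node x DNA-Molecule root
  node s DNA-Strand
  edge x has-part s
end

rule dna-strand-parts of DNA-Strand
  node x DNA-Strand root
  node g Gene
  edge x has-part g
end
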