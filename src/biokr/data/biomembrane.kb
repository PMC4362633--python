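; Biomembrane structure and function.
;
; Structure: every biomembrane has a phospholipid bilayer and a glycoprotein
; as parts, the glycoprotein is inside the bilayer, and the bilayer has
; exactly two phospholipid layers as regions.
;
; Function: every biomembrane has the function to allow Move-Through of the
; chemical entities it is permeable to, through its hydrophobic core (a
; region of its bilayer), and a Block function whose agent is the
; hydrophobic core, whose object is a hydrophilic compound and whose
; instrument is a fatty-acid tail. The membrane's selective permeability
; facilitates the Move-Through function.

class Biomembrane is-a Entity
class Phospholipid-Bilayer is-a Entity
class Phospholipid-Layer is-a Entity
class Glycoprotein is-a Entity
class Chemical-Entity is-a Entity
class Hydrophilic-Compound is-a Chemical-Entity
class Hydrophobic-Core is-a Spatial-Entity
class Fatty-Acid-Tail is-a Entity
class Selective-Permeability is-a Entity
class Polar-Molecule is-a Chemical-Entity disjoint-with Nonpolar-Molecule
class Nonpolar-Molecule is-a Chemical-Entity

rule biomembrane-structure of Biomembrane
  node x Biomembrane root
  node pb Phospholipid-Bilayer
  node gp Glycoprotein
  node pl Phospholipid-Layer
  edge x has-part pb
  edge x has-part gp
  edge gp is-inside pb
  edge pb has-region pl exactly 2
end

rule biomembrane-function of Biomembrane
  node x Biomembrane root
  node mt Move-Through
  node blk Block
  node ce Chemical-Entity
  node hc Hydrophobic-Core
  node pb Phospholipid-Bilayer
  node hpc Hydrophilic-Compound
  node fat Fatty-Acid-Tail
  node perm Selective-Permeability
  edge x has-function mt
  edge x has-function blk
  edge x permeable-to ce
  edge mt object ce
  edge mt site hc
  edge x has-part pb
  edge pb has-region hc
  edge blk agent hc
  edge blk object hpc
  edge blk instrument fat
  edge x possesses perm
  edge perm facilitates mt
end
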