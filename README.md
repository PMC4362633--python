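# biokr

Frame-style knowledge representation and question answering for biology
textbook knowledge: **graph-structured existential class rules** with
**Skolemized inheritance** over a small CLIB-style upper ontology, a
reasoner that answers the classic ontology question families (part-whole,
taxonomy, cardinality, description, comparison, relationship paths), and
exporters to OWL2 functional syntax (lossy, with loss accounting) and to
non-lossy first-order text.

## Who this is for

Knowledge engineers and ontologists who need class descriptions richer than
description logics allow. A universal statement such as *"every eukaryotic
cell has a ribosome, a nucleus and a eukaryotic chromosome such that the
chromosome is inside the nucleus"* is, as a class axiom,

```
∀x ∃y₁y₂y₃  Eukaryotic-Cell(x) →
    has-part(x,y₁) ∧ Ribosome(y₁) ∧
    has-part(x,y₂) ∧ Nucleus(y₂) ∧
    has-part(x,y₃) ∧ Eukaryotic-Chromosome(y₃) ∧ contains(y₂,y₃)
```

whose variable graph is **not a tree**: y₃ has two incoming edges (from x
and from the nucleus y₂). Tree-shaped formalisms (OWL class expressions)
cannot express this without loss. biokr stores such rules natively,
**Skolemizes** them — each existential yᵢ becomes a function term over the
root, e.g. `chromosome-of(x)` — and lets a subclass *specialize* an
inherited filler instead of duplicating it by declaring a term equality
(`eukaryotic-chromosome-of(x) = chromosome-of(x)`). The same equality can
also be *inferred* from an `exactly 1` cardinality constraint.

Queries are answered by **elaboration**: build a sample instance of the
class, apply every applicable rule, merge equality-linked Skolem terms with
union-find, and read answers off the resulting instance graph.

## Worked example

```python
from biokr import (load_example_kb, query_relation_values, elaborate,
                   find_relationship, cardinality_query)

kb = load_example_kb("cell-a1-a4")

# Q1: what are the parts of a cell?
print(sorted(query_relation_values(kb, "Cell", "has-part")))
# [('Chromosome', 'has-part'), ('Ribosome', 'has-part')]

# the elaborated eukaryotic cell: one chromosome individual, two labels
g = elaborate(kb, "Eukaryotic-Cell", 1)
chrom = g.instances_of(kb, "Chromosome")[0]
print(sorted(chrom.class_labels))
# ['Chromosome', 'Eukaryotic-Chromosome']

# Q6: how are DNA and a gene related?
dna = load_example_kb("dna-gene")
print(find_relationship(dna, "DNA-Molecule", "Gene")[0])
# dm1 --has-part--> dna-strand-of@dna-molecule-parts(dm1) --has-part--> gene-of@dna-strand-parts(dna-strand-of@dna-molecule-parts(dm1))

# Q3: how many layers does a phospholipid bilayer have?
mb = load_example_kb("biomembrane")
print(cardinality_query(mb, "Phospholipid-Bilayer", "has-region", "Phospholipid-Layer"))
# exactly 2
```

The one chromosome individual is the point: the subclass's chromosome and
the filler inherited from `Cell` were merged through the declared equality,
so the description *specializes* rather than duplicates. The same queries
are available from the shell:

```bash
biokr query parts Cell --kb cell-a1-a4
biokr query path DNA-Molecule Gene --kb dna-gene --json
biokr export cell-a1-a4 --format owl2     # prints a loss report on stderr
biokr synth --seed 7                      # a random valid KB, reproducibly
```

## Bundled knowledge bases

| name | contents |
|---|---|
| `upper-ontology` | Entity/Event/Relation/Role, an Action vocabulary, participant roles (agent, object, instrument, …), structural (`has-structure` → has-part, has-region, material, possesses), spatial and functional relations |
| `cell-a1-a4` | the cell / eukaryotic-cell rules with the Skolem equality |
| `biomembrane` | membrane structure (bilayer with exactly 2 layers, glycoprotein inside it) and functions (Block with its participants; Move-Through facilitated by selective permeability) |
| `plant-cell` | cell-wall synthesis (result is part of the agent — a cyclic rule), wall support with strong intensity, Protoplast as a cell *without* a wall (`exactly 0`) |
| `dna-gene` | the molecule → strand → gene part chain |

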