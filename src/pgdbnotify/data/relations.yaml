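# Interest-closure relation configuration.
#
# Each closure type is an ordered list of traversal rules applied to a
# fixed point.  Rule fields:
#   name      - relation label used in provenance paths
#   classes   - classes of the object the rule applies to (forward: the
#               member being expanded; reverse: the holder being pulled in)
#   slot      - slot name followed (forward) or scanned (reverse)
#   direction - forward: add the slot's values of a member;
#               reverse: add every listed-class object whose slot names a member
#   anchor_only - reverse rule matches only the closure anchor (default false)
#
# Transitivity needs no flag: the fixed point re-applies every rule to new
# members, so chains (complexes of complexes, nested sub-pathways) expand
# until no growth.  Pathways reached from a gene are members but are not
# expansion roots here because no gene rule fires on class PATHWAY.
gene:
  - {name: product, classes: [GENE], slot: PRODUCT, direction: forward}
  - {name: component-of, classes: [PROTEIN, COMPLEX], slot: COMPONENT-OF, direction: forward}
  - {name: catalyzes, classes: [PROTEIN, COMPLEX], slot: CATALYZES, direction: forward}
  - {name: reaction, classes: [ENZYMATIC-REACTION], slot: REACTION, direction: forward}
  - {name: in-pathway, classes: [REACTION], slot: IN-PATHWAY, direction: forward}
  - {name: regulated-by, classes: [REGULATION], slot: REGULATED-ENTITY, direction: reverse}
  - {name: transcription-unit, classes: [TRANSCRIPTION-UNIT], slot: GENES, direction: reverse, anchor_only: true}
pathway:
  - {name: reaction-list, classes: [PATHWAY], slot: REACTION-LIST, direction: forward}
  - {name: substrate-left, classes: [REACTION], slot: LEFT, direction: forward}
  - {name: substrate-right, classes: [REACTION], slot: RIGHT, direction: forward}
  - {name: catalyzed-by, classes: [ENZYMATIC-REACTION], slot: REACTION, direction: reverse}
  - {name: enzyme-of, classes: [PROTEIN, COMPLEX], slot: CATALYZES, direction: reverse}
  - {name: components, classes: [PROTEIN, COMPLEX], slot: COMPONENTS, direction: forward}
  - {name: gene-of, classes: [PROTEIN], slot: GENE, direction: forward}
  - {name: regulated-by, classes: [REGULATION], slot: REGULATED-ENTITY, direction: reverse}
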