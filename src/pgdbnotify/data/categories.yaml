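# Reader-facing change categories keyed by slot name.  A slot absent from
# this map renders as its own name in lowercase.  The report module reuses
# this map verbatim so diff classification and email wording cannot drift.
COMMENT: textual summary
GO-TERMS: GO term annotations
REGULATED-BY: regulation
REGULATED-ENTITY: regulation
CATALYZES: enzymatic activity
REACTION: enzymatic activity
REACTION-LIST: pathway structure
CITATIONS: citations
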