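# Database: ECOLI
# Version: 1.0
#
UNIQUE-ID - TRPA
TYPES - GENE
COMMON-NAME - trpA
PRODUCT - TRPA-MONOMER
CITATIONS - PMID:101
//
UNIQUE-ID - TRPA-MONOMER
TYPES - PROTEIN
GENE - TRPA
//
UNIQUE-ID - PUB-1
TYPES - PUBLICATION
PMID - 101
//
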