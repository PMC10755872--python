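# Functional-group registry and vapor-pressure contribution terms.
#
# This file is the single source of truth shared by the group counter and the
# volatility calculator.  Each entry defines one functional group:
#
#   id          stable key used in count tables and contribution breakdowns
#   k           index of the group in the underlying group-contribution scheme
#               (absent for groups added by analogy, which have no index there)
#   b           contribution term b_k, log10 atm per occurrence
#   source      pankow_asher for empirically fitted terms; assumed_* for terms
#               assigned by structural analogy (group-15 P~N, heteroatom S~N,
#               same group on C vs S) pending experimental validation
#   method      atom_count | ring_analysis | bond_analysis |
#               substructure_pattern | not_counted
#   smarts      SMARTS pattern (substructure_pattern only).  Patterns are
#               written so that only the essential heteroatoms/carbonyl
#               carbons are match atoms; anchoring carbons are expressed as
#               recursive constraints so they are not masked from later groups.
#   precedence  lower numbers are matched first and their atoms are masked
#               from later patterns, preventing composite groups (e.g. an
#               ester) from also being counted as their sub-groups (ether,
#               ketone).
#   raw_id      key under which the raw (pre-correction) count is stored when
#               the group participates in a double-counting correction rule
#   ignore_mask_from   groups whose masked atoms this pattern may still match;
#               used for the raw/corrected pairs where the correction rule,
#               not masking, resolves the overlap (phenol vs hydroxyl,
#               phosphoric ester vs phosphoric acid)
#
# Editing b values here (or overriding them at runtime) changes the model;
# the assumed terms in particular are expected to be revised as experimental
# values appear.

b0: 1.79

groups:
  - id: carbon
    k: 1
    b: -0.438
    source: pankow_asher
    method: atom_count

  - id: aromatic_ring
    k: 3
    b: -0.675
    source: pankow_asher
    method: ring_analysis

  - id: non_aromatic_ring
    k: 4
    b: -0.0104
    source: pankow_asher
    method: ring_analysis
    raw_id: ring_raw

  - id: carbon_double_bond
    k: 5
    b: -0.105
    source: pankow_asher
    method: bond_analysis
    raw_id: cdb_raw

  - id: hydroxyl
    k: 7
    b: -2.23
    source: pankow_asher
    method: substructure_pattern
    smarts: "[OX2H1;$([OX2H1][#6])]"
    precedence: 150
    raw_id: hydroxyl_raw
    ignore_mask_from: [phenol]

  - id: aldehyde
    k: 8
    b: -1.35
    source: pankow_asher
    method: substructure_pattern
    smarts: "[$([CX3H1](=[OX1])[#6]),$([CX3H2]=[OX1])]"
    precedence: 120

  - id: ketone
    k: 9
    b: -0.935
    source: pankow_asher
    method: substructure_pattern
    smarts: "[CX3;$([CX3](=[OX1])([#6])[#6])]"
    precedence: 130

  - id: carboxylic_acid
    k: 10
    b: -3.58
    source: pankow_asher
    method: substructure_pattern
    smarts: "[CX3](=[OX1])[OX2H1]"
    precedence: 70

  - id: ester
    k: 11
    b: -1.20
    source: pankow_asher
    method: substructure_pattern
    smarts: "[CX3](=[OX1])[OX2;H0][#6]"
    precedence: 90

  - id: ether
    k: 12
    b: -0.718
    source: pankow_asher
    method: substructure_pattern
    smarts: "[O;X2;H0;$([OX2]([#6])[#6])]"
    precedence: 170

  - id: ether_alicyclic
    k: 13
    b: -0.683
    source: pankow_asher
    method: not_counted

  - id: ether_aromatic
    k: 14
    b: -1.03
    source: pankow_asher
    method: not_counted

  - id: nitrate
    k: 15
    b: -2.23
    source: pankow_asher
    method: substructure_pattern
    smarts: "[OX2;$([OX2][#6])][NX3,NX3+;$([N](~[OX1])~[OX1])](~[OX1])~[OX1]"
    precedence: 10

  - id: nitro
    k: 16
    b: -2.15
    source: pankow_asher
    method: substructure_pattern
    smarts: "[NX3,NX3+;$([N](~[OX1])~[OX1]);$([N][#6])](~[OX1])~[OX1]"
    precedence: 20

  - id: phenol
    k: 17
    b: -2.14
    source: pankow_asher
    method: substructure_pattern
    smarts: "[OX2H1;$([OX2H1][c])]"
    precedence: 140

  - id: amine_primary
    k: 18
    b: -1.03
    source: pankow_asher
    method: substructure_pattern
    smarts: "[NX3;H2;!$([NX3][c]);$([NX3][C])]"
    precedence: 180

  - id: amine_secondary
    k: 19
    b: -0.849
    source: pankow_asher
    method: substructure_pattern
    smarts: "[NX3;H1;!$([NX3][c]);$([NX3]([C])[C])]"
    precedence: 181

  - id: amine_tertiary
    k: 20
    b: -0.608
    source: pankow_asher
    method: substructure_pattern
    smarts: "[NX3;H0;!$([NX3][c]);!$([NX3+]);$([NX3]([C])([C])[C])]"
    precedence: 182

  - id: amine_aromatic
    k: 21
    b: -1.61
    source: pankow_asher
    method: not_counted

  - id: amide
    k: 22
    b: -2.23
    source: assumed_group15_analogy
    method: substructure_pattern
    smarts: "[CX3](=[OX1])[NX3]"
    precedence: 100

  - id: peroxide
    k: 26
    b: -0.368
    source: pankow_asher
    method: substructure_pattern
    smarts: "[OX2;$([OX2]([#6])[OX2])][OX2;$([OX2]([#6])[OX2])]"
    precedence: 110

  - id: hydroperoxide
    k: 27
    b: -2.48
    source: pankow_asher
    method: not_counted

  - id: nitrophenol
    k: 29
    b: 0.0432
    source: pankow_asher
    method: not_counted

  - id: nitroester
    k: 30
    b: -2.67
    source: pankow_asher
    method: not_counted

  - id: phosphoric_acid
    b: -2.23
    source: assumed_group15_analogy
    method: substructure_pattern
    smarts: "[PX4;$([PX4](~[OX1])[OX2H1]),$([PX4](~[OX1])[OX1-])]"
    precedence: 40
    raw_id: phosphoric_acid_raw
    ignore_mask_from: [phosphoric_ester]

  - id: phosphoric_ester
    b: -2.23
    source: assumed_group15_analogy
    method: substructure_pattern
    smarts: "[PX4;$([PX4](~[OX1])[OX2][#6])]"
    precedence: 30

  - id: phosphate
    b: -2.23
    source: assumed_group15_analogy
    method: not_counted

  - id: sulfate
    b: -2.23
    source: assumed_heteroatom_analogy
    method: substructure_pattern
    smarts: "[SX4;$([SX4](~[OX1])(~[OX1])([OX2,OX1-])[OX2][#6])]"
    precedence: 50

  - id: sulfonate
    b: -2.23
    source: assumed_heteroatom_analogy
    method: substructure_pattern
    smarts: "[SX4;$([SX4](~[OX1])(~[OX1])([OX2,OX1-])[#6])]"
    precedence: 60

  - id: thiol
    b: -2.23
    source: assumed_carbon_sulfur_analogy
    method: substructure_pattern
    smarts: "[SX2H1;$([SX2H1][#6])]"
    precedence: 160

  - id: carbothioester
    b: -1.20
    source: assumed_carbon_sulfur_analogy
    method: substructure_pattern
    smarts: "[CX3](=[OX1])[SX2][#6]"
    precedence: 80
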