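# Default trait_id -> theme map for Ethnographic Atlas variables (D-PLACE ids).
# This grouping is an editable approximation: kinship covers marriage, family
# construction, community organisation and residence; economic covers
# subsistence, food production, division of labour and inheritance.
# Override with your own map for a different trait set.
themes:
  EA008: kinship   # domestic organization
  EA009: kinship   # marital composition: monogamy and polygamy
  EA011: kinship   # transfer of residence at marriage
  EA012: kinship   # marital residence with kin
  EA015: kinship   # community marriage organization
  EA023: kinship   # cousin marriages permitted
  EA027: kinship   # kin terms for cousins
  EA043: kinship   # descent: major type
  EA001: economic  # subsistence economy: gathering
  EA002: economic  # subsistence economy: hunting
  EA003: economic  # subsistence economy: fishing
  EA004: economic  # subsistence economy: animal husbandry
  EA005: economic  # subsistence economy: agriculture
  EA028: economic  # intensity of agriculture
  EA042: economic  # dominant subsistence activity
  EA054: economic  # sex differences: agriculture
  EA074: economic  # inheritance rule for real property
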