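schema_version: "1"
# First rough draft tree for metastatic pancreatic cancer, kept verbatim
# with its known imperfections so the validation layer has a realistic
# defective input: two undifferentiated recommendations for fit patients,
# an overlap that leaves unclear when GEM rather than BSC applies, and an
# uncovered unfit/younger combination (age and fitness never cleanly
# separated).
participant:
  id: draft-pancreatic
criteria:
  - name: fitness
    levels: [fit, unfit]
  - name: age
    levels: ["<70", ">=70"]
tree:
  criterion: fitness
  branches:
    - levels: [fit]
      node:
        recommendations: [GEM, FOLFIRINOX]
        multiplicity: single
    - levels: [unfit]
      node:
        criterion: age
        branches:
          - levels: [">=70"]
            node:
              recommendations: [BSC]
              multiplicity: single
          - levels: [">=70"]
            node:
              recommendations: [GEM]
              multiplicity: single
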