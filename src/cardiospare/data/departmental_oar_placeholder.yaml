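# SYNTHETIC PLACEHOLDER departmental OAR table.
#
# Departmental planning constraints are clinic-specific and no authoritative
# table ships with this package.  These rows are generic lung-SBRT-style EQD2
# limits for the organs the phantom cohort contains; REVIEW AND OVERRIDE them
# with your own departmental table before drawing clinical conclusions.
constraints:
  - structure: spinal_cord
    metric: D0.1cc
    optimal: 40.0
    mandatory: null
    alpha_beta: 2.0
    source: placeholder (synthetic)
  - structure: esophagus
    metric: D0.1cc
    optimal: 65.0
    mandatory: null
    alpha_beta: 2.0
    source: placeholder (synthetic)
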