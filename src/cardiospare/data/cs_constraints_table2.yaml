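# Literature dose constraints for cardiac (sub-)structures, in EQD2 Gy.
# Limits are "optimal (mandatory)"; comparison is strict '<' (equality counts
# as violated).  Structures without a published alpha/beta use the generic
# 2 Gy.  base_of_heart = right atrium ∪ ascending aorta.
constraints:
  - structure: base_of_heart
    metric: D0.1cc
    optimal: 13.5
    mandatory: null
    alpha_beta: 2.0
    source: McWilliam 2020
  - structure: heart
    metric: D60%
    optimal: 1.0
    mandatory: null
    alpha_beta: 2.0
    source: Stam 2017
  - structure: left_atrium
    metric: D0.1cc
    optimal: 4.7
    mandatory: 6.5
    alpha_beta: 2.0
    source: Stam 2017
  - structure: right_ventricle
    metric: D4%
    optimal: 11.0
    mandatory: 13.3
    alpha_beta: 2.0
    source: Chan 2020
  - structure: left_ventricle
    metric: D0.1cc
    optimal: 60.0
    mandatory: null
    alpha_beta: 2.0
    source: Jang 2020
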