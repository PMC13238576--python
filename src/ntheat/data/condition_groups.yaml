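# ICD-10-AM emergency-care shortlist condition groups, in lookup order.
# A 3-character range matches all decimal children of its stems; a
# decimal-specific entry (or decimal range) matches only the listed codes.
- name: infectious
  label: Infectious
  codes: [A00-A99, B00-B99, U07.1-U07.2]
- name: diabetes
  label: Diabetes
  codes: [E10-E11, E14]
- name: mental_behavioural
  label: Mental/behavioural
  codes: [F00-F99, R44, R45]
- name: cardiovascular
  label: Cardiovascular
  codes: [I00-I51, R00.1-R00.2, R07.1, R07.4]
- name: respiratory
  label: Respiratory
  codes: [J00-J99, R04.0, R04.2, R05, R06.0-R06.2, R06.4, R06.8, R07.0, R09.1, R09.2, R09.89]
- name: digestive
  label: Digestive
  codes: [K00-K92, R10, R11, R13, R17, R18, R19.0, R19.89]
- name: skin
  label: Skin
  codes: [L00-L98, R20.8, R21, R22.9, R23.8]
- name: musculoskeletal
  label: Musculoskeletal
  codes: [M00-M95, R25.2, R26.8, R29.89]
- name: urinary
  label: Urinary
  codes: [N00-N39]
- name: injury
  label: Injury
  codes: [S00-S99, T00-T66, T68-T88]
- name: effects_heat_light
  label: Effects heat and light
  codes: [T67]
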