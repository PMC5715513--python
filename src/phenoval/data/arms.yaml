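# The five shipped phenotyping arms: certainty requirement plus imaging
# linkage (not_required / any / integer window half-width in days).
- name: definite
  certainty: definite
  imaging: not_required
- name: definite_any
  certainty: definite
  imaging: any
- name: definite_w30
  certainty: definite
  imaging: 30
- name: definite_w1
  certainty: definite
  imaging: 1
- name: suspected_any
  certainty: suspected
  imaging: any
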