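# Named ICD-10 code sets used by the stroke-code validation pipeline.
# exact_codes match whole normalized codes; category_prefixes match any code
# in a 3-character category; category_ranges match categories inclusively.
stroke:
  category_prefixes: [I60, I61, I63]
  exact_codes: [G458, G459]
hypertension:
  category_ranges: [[I10, I15]]
diabetes:
  category_ranges: [[E10, E14]]
dyslipidemia:
  category_prefixes: [E78]
atrial_fibrillation:
  category_prefixes: [I48]
brain_metastases:
  exact_codes: [C793]
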