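"""Deterministic fixture pushed through the whole pipeline.

The exact-count fixture emulates a hospital cancer-registry extract whose
pipeline output is known in advance: registry cleaning, stroke-code
extraction, same-day deduplication, and imaging-linkage arm classification
should land on the configured counts exactly.
"""

import phenoval as pv

bundle, truth = pv.generate_fixture(pv.load_fixture_spec())
print(f"registry rows:            {len(bundle.patients)}")

clean = pv.clean_registry(bundle.patients)
print(f"retained after cleaning:  {len(clean.retained)} "
      f"(excluded {pv.exclusion_summary(clean.log)})")

stroke = pv.extract_codes(bundle.diagnoses, pv.default_code_sets()["stroke"])
print(f"stroke-code records:      {len(stroke)}")

deduped = pv.dedup_diagnoses(stroke)
by_certainty = deduped["certainty"].value_counts().to_dict()
print(f"after same-day dedup:     {by_certainty}")

assignments = pv.classify_arms(deduped, bundle.procedures)
print(f"arm sizes:                {pv.arm_counts(assignments)}")
print(f"imaging orders:           {len(bundle.procedures)}")
print("\nEvery count is produced by the pipeline itself; the fixture only "
      "controls\nhow many events, duplicates, and imaging offsets exist "
      "upstream.")
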