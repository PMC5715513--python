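# Exact-count fixture: a deterministic bundle whose pipeline output
# reproduces the study's flow counts (FixtureSpec fields).
registry_rows: 27932
duplicate_rows: 2083
invalid_rows: 22
distinct_definite: 912
total_definite: 1991
distinct_suspected: 228
total_suspected: 663
imaging_any: 438
imaging_w30: 239
imaging_w1: 212
imaging_orders_total: 4544
seed: 0
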