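# Illustrative per-model token prices (per 1,000,000 tokens).
# Real platform quotes vary by vendor and date; substitute your own.
model-a: {input_per_mtok: 0.11, output_per_mtok: 0.28, currency: USD}
model-b: {input_per_mtok: 0.07, output_per_mtok: 0.27, currency: USD}
model-c: {input_per_mtok: 0.08, output_per_mtok: 0.33, currency: USD}
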