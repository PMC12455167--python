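# Example screening run configuration.
# The PICOS block drives both the prompts and (via keyword matching) the
# offline mock backend; model names and prices below are illustrative only.
picos:
  population: hepatocellular carcinoma cirrhosis unresectable
  intervention: resection ablation chemoembolization lenvatinib sorafenib
  outcome: survival recurrence
  study_design: randomized controlled
roles:
  reviewer:
    model_name: model-a
    model_kind: general-purpose
    input_price_per_mtok: 0.11
    output_price_per_mtok: 0.28
  critic:
    model_name: model-b
    model_kind: general-purpose
    input_price_per_mtok: 0.07
    output_price_per_mtok: 0.27
  arbitrator:
    model_name: model-c
    model_kind: reasoning-optimized
    input_price_per_mtok: 0.08
    output_price_per_mtok: 0.33
batch_size: 10
max_retries: 2
critic_sees_reasoning: true
filter_blank_abstracts: true
mock:
  threshold: 2
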