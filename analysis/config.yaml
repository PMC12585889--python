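# Demo-scale cohort for the numbered analysis scripts.
# The acceptance script and the test suite run the full study conditions
# (20 identities, 10 observers per source); this keeps the walkthrough quick.
seed: 0
n_identities: 10
observers_per_source: 4
image_size: 224
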