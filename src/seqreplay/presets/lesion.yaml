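# Hippocampus-to-cortex feedback lesioned before training: hippocampal
# replays persist but the cortical representation cannot develop.
name: lesion
seed: 42
nights: 4
hc_to_ctx_enabled: false
days:
  - train: [{seq: ABCDE, trials: 10}]
    test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
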