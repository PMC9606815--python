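# Intact network with hippocampal learning disabled during sleep: the
# hippocampal trace decays night after night, yet its replays still train
# the cortex until the memory is hippocampus-independent.
name: hc_sleep_off
seed: 42
nights: 4
gates: {hc_learning_sleep: false}
days:
  - train: [{seq: ABCDE, trials: 10}]
    test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
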