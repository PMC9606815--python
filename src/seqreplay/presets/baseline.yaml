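# Intact network: one sequence trained on Day 1, consolidated over four
# nights of slow-wave sleep, tested each morning thereafter.
name: baseline
seed: 42
nights: 4
days:
  - train: [{seq: ABCDE, trials: 10}]
    test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
  - test: [{cue: A, target: ABCDE}]
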