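# Two sequences sharing their third item (C), trained together on four
# consecutive days with nightly sleep and end-of-day recall tests.
name: overlap
seed: 42
nights: 4
days:
  - train: [{seq: ABCDE, trials: 10}, {seq: FGCIJ, trials: 10}]
    test: [{cue: A, target: ABCDE}, {cue: F, target: FGCIJ}]
  - train: [{seq: ABCDE, trials: 10}, {seq: FGCIJ, trials: 10}]
    test: [{cue: A, target: ABCDE}, {cue: F, target: FGCIJ}]
  - train: [{seq: ABCDE, trials: 10}, {seq: FGCIJ, trials: 10}]
    test: [{cue: A, target: ABCDE}, {cue: F, target: FGCIJ}]
  - train: [{seq: ABCDE, trials: 10}, {seq: FGCIJ, trials: 10}]
    test: [{cue: A, target: ABCDE}, {cue: F, target: FGCIJ}]
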