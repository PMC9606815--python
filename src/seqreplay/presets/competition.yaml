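# Competition for replay opportunities: the rival sequence FGHIJ keeps being
# practiced on Days 2-4, crowding ABCDE out of sleep replay and leaving it
# unconsolidated (daily recall of ABCDE is probed throughout).
name: competition
seed: 42
nights: 4
days:
  - train: [{seq: ABCDE, trials: 10}, {seq: FGHIJ, trials: 10}]
    test: [{cue: A, target: ABCDE}]
  - train: [{seq: FGHIJ, trials: 10}]
    test: [{cue: A, target: ABCDE, when: morning}]
  - train: [{seq: FGHIJ, trials: 10}]
    test: [{cue: A, target: ABCDE, when: morning}]
  - train: [{seq: FGHIJ, trials: 10}]
    test: [{cue: A, target: ABCDE, when: morning}]
  - test: [{cue: A, target: ABCDE}]
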