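# Two non-overlapping sequences trained on Day 1; only the first is
# rehearsed on Days 2-4, so its salience -- and its share of the 50 nightly
# replay opportunities -- grows night after night.
name: salience_two_seq
seed: 42
nights: 4
days:
  - train: [{seq: ABCDE, trials: 10}, {seq: FGHIJ, trials: 10}]
  - train: [{seq: ABCDE, trials: 10}]
  - train: [{seq: ABCDE, trials: 10}]
  - train: [{seq: ABCDE, trials: 10}]
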