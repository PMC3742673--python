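{
  "description": "Sign convention for the simulated (all-atom MD derived) residue-pair minimum interaction magnitudes: like-charge pairs are repulsive (positive), every other pair is attractive (negative).",
  "positive_pairs": [["D", "D"], ["D", "E"], ["E", "E"], ["R", "R"], ["R", "K"], ["K", "K"]]
}
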