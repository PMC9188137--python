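# Bundled example spaced-seed pattern sets, grouped by weight.
#
# These are synthetic fixtures: representative low-self-overlap patterns of
# the stated weights, found by a randomized search minimizing the pattern's
# shift-autocorrelation (patterns with low self-overlap distribute their hits
# more evenly and tend to be more sensitive).  They are NOT the output of any
# external pattern optimizer; only their weights and count are contractual.
weight15:
  - {id: w15a, bits: "1110011011110110101101"}
  - {id: w15b, bits: "10101100111111100011101"}
  - {id: w15c, bits: "111101110001101100001111"}
  - {id: w15d, bits: "1111001011001110001111001"}
weight14:
  - {id: w14a, bits: "111000111100111100111"}
  - {id: w14b, bits: "1011011001111000111101"}
  - {id: w14c, bits: "10100101001101110011111"}
  - {id: w14d, bits: "101101011110011000100111"}
weight8:
  - {id: w8a, bits: "1100101110101"}
  - {id: w8b, bits: "11011100110001"}
  - {id: w8c, bits: "101000111010011"}
  - {id: w8d, bits: "1011010100100101"}
weight19:
  - {id: w19a, bits: "1000110111111011110011101101"}
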