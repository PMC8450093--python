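{
  "description": "disl-2-like total small-RNA library: 65% of antisense rDNA mass placed in the 26S region. Weights other than the 26S share are schematic parameters, not measured truths.",
  "fractions": {
    "risiRNA": 0.35,
    "sense_rRNA": 0.30,
    "sense_mRNA": 0.20,
    "antisense_mRNA": 0.05,
    "unmapped": 0.10
  },
  "region_weights": {
    "5ETS": 0.04,
    "18S": 0.10,
    "ITS1": 0.06,
    "5.8S": 0.02,
    "ITS2": 0.06,
    "26S": 0.65,
    "3ETS": 0.07
  },
  "p_first_G": 0.75
}
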