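{
  "description": "dis-3-like total small-RNA library: a large fraction of antisense rDNA reads placed in the internal transcribed spacers (ITS1/ITS2). Exact weights are schematic parameters.",
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
    "ITS1": 0.35,
    "5.8S": 0.03,
    "ITS2": 0.30,
    "26S": 0.15,
    "3ETS": 0.03
  },
  "p_first_G": 0.75
}
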