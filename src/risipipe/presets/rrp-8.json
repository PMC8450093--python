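{
  "description": "rrp-8-like total small-RNA library: 26S-skewed antisense placement. Exact weights are schematic parameters.",
  "fractions": {
    "risiRNA": 0.35,
    "sense_rRNA": 0.30,
    "sense_mRNA": 0.20,
    "antisense_mRNA": 0.05,
    "unmapped": 0.10
  },
  "region_weights": {
    "5ETS": 0.05,
    "18S": 0.10,
    "ITS1": 0.08,
    "5.8S": 0.02,
    "ITS2": 0.08,
    "26S": 0.55,
    "3ETS": 0.12
  },
  "p_first_G": 0.75
}
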