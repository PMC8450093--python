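{
  "description": "Default total small-RNA library with canonical 22G structure: antisense rDNA reads peak at 22 nt with a 5'-G bias, on a broad region-weight background.",
  "fractions": {
    "risiRNA": 0.40,
    "sense_rRNA": 0.25,
    "sense_mRNA": 0.20,
    "antisense_mRNA": 0.05,
    "unmapped": 0.10
  },
  "region_weights": {
    "5ETS": 0.10,
    "18S": 0.20,
    "ITS1": 0.10,
    "5.8S": 0.03,
    "ITS2": 0.10,
    "26S": 0.40,
    "3ETS": 0.07
  },
  "p_first_G": 0.75
}
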