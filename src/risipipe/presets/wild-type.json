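{
  "description": "Wild-type-like total small-RNA library: antisense rDNA reads are rare; the library is dominated by sense degradation fragments.",
  "fractions": {
    "risiRNA": 0.02,
    "sense_rRNA": 0.55,
    "sense_mRNA": 0.30,
    "antisense_mRNA": 0.03,
    "unmapped": 0.10
  },
  "region_weights": {
    "5ETS": 0.10,
    "18S": 0.25,
    "ITS1": 0.10,
    "5.8S": 0.05,
    "ITS2": 0.10,
    "26S": 0.30,
    "3ETS": 0.10
  },
  "p_first_G": 0.75
}
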