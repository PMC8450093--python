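{
  "description": "eri-1;rrp-8 NRDE-3-immunoprecipitation library: the IP enriches antisense rDNA reads, and 90% of their mass is placed in the 26S region.",
  "fractions": {
    "risiRNA": 0.70,
    "sense_rRNA": 0.10,
    "sense_mRNA": 0.05,
    "antisense_mRNA": 0.05,
    "unmapped": 0.10
  },
  "region_weights": {
    "5ETS": 0.01,
    "18S": 0.03,
    "ITS1": 0.02,
    "5.8S": 0.01,
    "ITS2": 0.02,
    "26S": 0.90,
    "3ETS": 0.01
  },
  "p_first_G": 0.75
}
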