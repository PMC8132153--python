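{
  "intercept": -1.9,
  "coefficients": {
    "ST6GAL2": 21.8,
    "POM121": 21.4,
    "MID2": 21.3,
    "MIDN": 21.1,
    "HDAC11": 20.8,
    "FOXD4L3": 20.7,
    "MTMR9": 20.7,
    "WIPF2": 20.6,
    "SEMA4C": 20.5,
    "COL18A1": 19.0,
    "RLF": 15.9,
    "SALL3": 4.7,
    "ANKDD1B": 2.4,
    "BCL9L": 1.6,
    "VPS13C": 1.3
  },
  "cutoff": 8.4,
  "provenance": {
    "source": "published 15-gene cervical-cancer NACT C-classifier (printed coefficients)"
  }
}
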