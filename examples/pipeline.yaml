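# End-to-end synthetic discovery + validation run (C-classifier path).
seed: 11
training:
  simulate:
    n_nonresponder: 30
    n_responder: 26
    n_genes: 200
    background_rate: 0.03
    causal_genes:
      - [G0001, 0.45, 0.04]
      - [G0002, 0.45, 0.04]
      - [G0003, 0.45, 0.04]
      - [G0004, 0.45, 0.04]
      - [G0005, 0.45, 0.04]
      - [G0006, 0.45, 0.04]
validation:
  simulate:
    n_nonresponder: 22
    n_responder: 80
    n_genes: 200
    background_rate: 0.03
    causal_genes:
      - [G0001, 0.45, 0.04]
      - [G0002, 0.45, 0.04]
      - [G0003, 0.45, 0.04]
      - [G0004, 0.45, 0.04]
      - [G0005, 0.45, 0.04]
      - [G0006, 0.45, 0.04]
screen:
  simulate:
    n_genes: 200
    enriched_genes:
      G0001: 3.0
      G0002: 3.0
      G0003: 3.0
      G0004: 3.0
      G0005: 3.0
      G0006: 3.0
# reduced: true swaps the 200x10-fold cascade for the quick profile
reduced: true
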