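# NSY-5 (innexin) gap-junction subnetwork membership, by cell class.
# `classes` is the published class list for the left/right paired members;
# `pn_classes` are the classes in this subnetwork reported to follow the
# P-N wiring strategy (16 cells after L/R expansion).
classes:
  - ADA
  - ADF
  - ADL
  - AFD
  - AIM
  - AIZ
  - ASH
  - ASI
  - ASK
  - AWB
  - AWC
  - BAG
  - RIC
pn_classes:
  - ADA
  - AIY
  - AIZ
  - ASK
  - ADL
  - AFD
  - ASH
  - AWC
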