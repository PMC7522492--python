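# Printed cell-class membership of the five wiring strategies identified in
# the first-mover analysis of larval synaptogenesis. Class names are kept
# verbatim, including dorsal/ventral subclasses (e.g. IL2D) and the lateral
# IL2 pair written as IL2L/R.
NP:
  - ADF
  - ASI
  - AUA
  - AVA
  - AVB
  - AVD
  - AVE
  - DVA
  - DVC
  - IL2D
  - IL2L/R
  - IL2V
  - PVP
  - PVR
  - RIA
  - RIB
  - RIG
  - RIH
  - RIR
  - URB
  - URYD
  - URYV
XOR_FIRST:
  - ALM
  - BDU
  - DVC
  - IL2D
XOR_SECOND:
  - AVA
  - AVB
  - AVD
  - AVE
  - AWB
  - BAG
  - IL2L/R
  - RIA
  - URYD
  - URYV
XNOR:
  - ADF
  - ASI
  - DVA
  - IL2V
  - PVR
  - PVT
  - SAAD
  - SAAV
PN:
  - ADA
  - ADL
  - AFD
  - AIA
  - AIB
  - AIN
  - AIY
  - AIZ
  - ASE
  - ASG
  - ASH
  - ASJ
  - ASK
  - AWA
  - AWC
  - FLP
  - OLL
  - OLQD
  - OLQV
  - PVC
  - RIF
  - RIM
  - RIP
  - URX
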