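# Default amyloid-beta outcome block: 19 bilateral Desikan-Killiany regions
# (38 SUVR columns) covering the cortical families that make up a global
# amyloid composite — lateral and medial prefrontal, parietal, lateral
# temporal, and cingulate cortices.  The exact membership of a global-amyloid
# index varies between pipelines; replace this file to match yours.
name: abeta_global_composite
tracer: abeta
cortical:
  - superiorfrontal
  - rostralmiddlefrontal
  - caudalmiddlefrontal
  - parsopercularis
  - parstriangularis
  - parsorbitalis
  - lateralorbitofrontal
  - medialorbitofrontal
  - frontalpole
  - rostralanteriorcingulate
  - caudalanteriorcingulate
  - posteriorcingulate
  - isthmuscingulate
  - superiorparietal
  - inferiorparietal
  - supramarginal
  - precuneus
  - superiortemporal
  - middletemporal
subcortical: []
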