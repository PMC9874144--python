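# Default tau outcome block: 7 bilateral regions (14 SUVR columns) that
# accumulate tau early in preclinical Alzheimer's disease — Braak stage I
# (entorhinal cortex), stage III (amygdala, fusiform, parahippocampal and
# lingual gyri) and the temporal parts of stage IV (inferior and middle
# temporal gyri).  The hippocampus (Braak II) is deliberately absent because
# of off-target tracer binding in the adjacent choroid plexus.
name: tau_early_braak
tracer: tau
cortical:
  - entorhinal
  - parahippocampal
  - fusiform
  - lingual
  - inferiortemporal
  - middletemporal
subcortical:
  - amygdala
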