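# Sucrose soft drink, 400 mosm/L (136.92 g/L sucrose = 13.7% w/v).
label: Sucrose soft drink
volume_l: 0.5
declared_osmolarity_mosm_l: 400
components:
  - {solute: sucrose, concentration_g_per_l: 136.92}
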