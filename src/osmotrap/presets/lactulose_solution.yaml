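# Lactulose drink: a non-absorbable disaccharide acting as a persistent
# luminal osmotic load (136.92 g/L -> 400 mosm/L, computed).
label: Lactulose solution
volume_l: 0.5
components:
  - {solute: lactulose, concentration_g_per_l: 136.92}
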