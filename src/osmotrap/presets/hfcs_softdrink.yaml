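# HFCS soft drink: glucose 360 + fructose 440 = 800 mosm/L overall
# (55% fructose / 45% glucose by mass and by osmolar share).
label: HFCS soft drink
volume_l: 0.5
declared_osmolarity_mosm_l: 800
components:
  - {solute: glucose, concentration_g_per_l: 64.8576}
  - {solute: fructose, concentration_g_per_l: 79.2704}
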