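# WHO hypotonic oral rehydration solution: glucose 75 + salt 170 = 245 mosm/L.
label: WHO peroral rehydration solution
volume_l: 0.5
declared_osmolarity_mosm_l: 245
components:
  - {solute: glucose, concentration_g_per_l: 13.512}
  - {solute: nacl, concentration_g_per_l: 4.9674}
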