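# Salty commercial soup: quoted as ~1.3% NaCl with an overall 400 mosm/L.
# The NaCl concentration shipped here is the one whose ideal osmolarity is
# exactly 400 mosm/L (the 1.3% figure is a rounded label value).
label: Salty commercial soup
volume_l: 0.5
declared_osmolarity_mosm_l: 400
components:
  - {solute: nacl, concentration_g_per_l: 11.688}
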