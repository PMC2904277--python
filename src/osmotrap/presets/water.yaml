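label: Pure water
volume_l: 0.5
declared_osmolarity_mosm_l: 0
components: []
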