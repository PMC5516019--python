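# Symmetry classes of the homotetrameric Kv1.2 receptor: the 12 sevoflurane
# sites group into 3 distinguishable regions of 4 subunit copies each.
class_id	site_id
S6P-helix	1
S6P-helix	2
S6P-helix	3
S6P-helix	4
Ext-face	5
Ext-face	6
Ext-face	7
Ext-face	8
S4S5-linker	9
S4S5-linker	10
S4S5-linker	11
S4S5-linker	12
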