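gene_symbol	provenance
HLA-DRA	antigen_presentation_kegg
HLA-DQA	antigen_presentation_kegg
HLA-DQB	antigen_presentation_kegg
CIITA	antigen_presentation_kegg
B2M	both
TAP1	antigen_presentation_kegg
IRF2	crispr_screen_hit
IRF8	crispr_screen_hit
JAK2	crispr_screen_hit
PRKCD	crispr_screen_hit
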