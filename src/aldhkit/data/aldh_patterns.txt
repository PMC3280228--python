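# ALDH active-site patterns, PROSITE syntax (id<TAB>pattern per line).
# Curated approximations of the canonical ALDH cysteine / glutamic acid
# active-site signatures; pattern content is configuration and can be
# replaced with the canonical PROSITE definitions without code changes.
PS00070	[FYLVA]-x-{GVEP}-{DILV}-G-[QE]-{LPYG}-C-[LIVMGSTANC]-[AGCN]-{HE}-[GSTADNEKR]
PS00687	[LIVMFGA]-E-[LIMSTAC]-[GS]-G-[KNLM]-[SADN]-[TAPFV]
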