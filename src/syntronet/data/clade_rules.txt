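# Ordered clade rules: first match wins; pattern<TAB>label; unmatched -> other.
# Specific ANME subtypes before the ANME-1/-3 prefixes.
ANME-2a	ANME-2a
ANME-2b	ANME-2b
ANME-2c	ANME-2c
ANME-2d	ANME-2d
ANME-1	ANME-1
ANME-3	ANME-3
# SEEP-SRB1g before the broader SEEP-SRB1 prefix; Desulfococcus-labeled
# lineages are aliased into SEEP-SRB1g.
SEEP-SRB1g	SEEP-SRB1g
Desulfococcus	SEEP-SRB1g
SEEP-SRB1a	SEEP-SRB1a
SEEP-SRB2	SEEP-SRB2
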