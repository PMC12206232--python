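TGF_SIGNALING	illustrative TGF-beta receptor signaling set; replace with curated membership	TGFB1	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD4	SMAD7	SERPINE1	SKIL	TGIF1	JUNB	LTBP1
FIBROBLAST_ACTIVATION	illustrative activated-fibroblast set; user-supplied list recommended	ACTA2	COL1A1	COL1A2	COL3A1	FN1	POSTN	TNC	CTHRC1	SPARC	TIMP1	LOX	PDGFRB
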