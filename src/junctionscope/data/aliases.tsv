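symbol	canonical
KIAA1598	SHTN1
SHTN1	SHTN1
BRAF	BRAF
KIAA1549	KIAA1549
FGFR1	FGFR1
FGFR2	FGFR2
FGFR3	FGFR3
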