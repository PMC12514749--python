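dg	archer	arriba	starfusion	rtpcr
Astr. Gr2	KIAA1549::BRAF 16–11	KIAA1549::BRAF 16–11	X	KIAA1549::BRAF 16–11
PA	KIAA1549::BRAF 15–9	KIAA1549::BRAF 15–9	X	KIAA1549::BRAF 15–9
DA	KIAA1549::BRAF 15–9	KIAA1549::BRAF 15–9	X	KIAA1549::BRAF 15–9
PA	GNAI1::BRAF 1–10	GNAI1::BRAF 1–10	X	GNAI1::BRAF 1–10
PA	KIAA1549::BRAF 13–11	KIAA1549::BRAF 13–11	X	KIAA1549::BRAF 13–11
PA	X	KIAA1549::BRAF 15–9	X	KIAA1549::BRAF 15–9
PA	KIAA1549::BRAF 10–9	KIAA1549::BRAF 10–9	X	KIAA1549::BRAF 10–9
PA	KIAA1549::BRAF 16–9	KIAA1549::BRAF 16–9	X	KIAA1549::BRAF 16–9
Astr. Gr2	KIAA1549::BRAF 13–9	KIAA1549::BRAF 13–9	X	ND
GG	X	EPHB2::BRAF 9–10	EPHB2::BRAF	EPHB2::BRAF 9–10
PA	X	KIAA1549::BRAF 16–9	X	KIAA1549::BRAF 16–9
GG	X	NRF1::BRAF 10–10	X	ND
PA	KIAA1549::BRAF 15–9	X	X	KIAA1549::BRAF 15–9
PA	ETV6::NTRK3 5–15	ETV6::NTRK3 5–15	X	ND
PA	PDE4DIP::NTRK1 16–12	PDE4DIP::NTRK1 16–12	X	PDE4DIP::NTRK1 16–12
PA	NACC2::NTRK2 5–13	NACC2::NTRK2 5–13	X	NACC2::NTRK2 5–13
LGG NOS	X	PAG1::BRAF 5–9	PAG1::BRAF	PAG1::BRAF 5–9
GG	PPP1CB::ALK 5–20	PPP1CB::ALK 5–20	X	PPP1CB::ALK 5–20
GG	FGFR2::KIAA1598 17–7	FGFR2::KIAA1598 17–7	X	FGFR2::KIAA1598 17–7
PA	TAX1BP1::BRAF 5–9	TAX1BP1::BRAF 5–9	X	TAX1BP1::BRAF 5–9
DNET	X	truncat. MYBL1	X	ND
DNET	FGFR3::TACC3 17–10	FGFR3::TACC3 17–10	X	FGFR3::TACC3 17–10
GG	FGFR2::KIAA1598 17–7	FGFR2::KIAA1598 17–7	X	FGFR2::KIAA1598 17–7
DNET	FGFR2::ZCCHC24 17–2	FGFR2::ZCCHC24 17–2	X	FGFR2::ZCCHC24 17–2
PA	KIAA1549::BRAF 13–11	KIAA1549::BRAF 13–11	X	KIAA1549::BRAF 13–11
DNET	X	KDD FGFR1	X	KDD FGFR1
PA	X	KDD FGFR1	X	KDD FGFR1
PA	X	KDD FGFR1	X	KDD FGFR1
LGG	MKRN1::BRAF 4–11	X	X	MKRN1::BRAF 4–11
DNET	X	KDD FGFR1	X	KDD FGFR1
infant. glioma	GIT2::ROS1 16–36	GIT2::ROS1 16–36	X	GIT2::ROS1 16–36
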