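site_id	EH77	EH78	EH79	EH80	EH83	EH105	EH84	EH85	EH86	EH90	EH91	EH103	EH92	EH93	EH94	EH96	EH97	EH98	EH104	Picea_glauca
scf1:1023485	A	A	A	A	A	-	A	A	A	A	A	A	C	C	C	C	C	C	C	G
scf4:65316	G	G	-	G	G	G	-	G	-	-	G	-	T	T	T	T	T	-	T	G
scf6:194010	-	A	A	A	A	A	-	A	-	A	A	A	C	C	C	C	C	C	-	C
scf6:325675	C	C	C	C	-	-	-	-	C	C	C	C	A	-	A	A	A	A	A	C
scf11:95116	A	A	-	A	A	A	A	A	A	-	A	-	G	G	G	G	G	G	G	A
scf15:5654	A	A	A	A	A	A	-	A	A	A	A	A	-	-	C	C	C	C	C	A
scf17:36760	-	C	-	-	C	-	C	-	C	C	-	-	T	-	T	-	T	T	T	C
scf20:27703	A	A	-	A	-	-	-	-	-	A	A	A	C	-	C	-	C	C	C	A
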