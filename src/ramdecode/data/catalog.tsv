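gene	variant	phenotype	breeds	source	reported_prior
GDF9	R87H	None reported	Multiple	literature; this panel	yes
GDF9	E241K	None reported	Multiple	literature; this panel	yes
GDF9	R315C	Fecundity, Vacaria, FecG^V	Ile de France	literature	yes
GDF9	V332I	None reported	Multiple	literature; this panel	yes
GDF9	F345C	Fecundity, Embrapa, FecG^E	Santa Ines	literature	yes
GDF9	V371M	Fecundity	Finnish landrace	literature; this panel	yes
GDF9	S395F	Fecundity, High Fertility, FecG^H	Belclare, Cambridge	literature	yes
GDF9	S427R	Fecundity, Thoka, FecT^T	Icelandic	literature	yes
BMP15	L11ΔL	None reported	Multiple	literature; this panel	yes
BMP15	R67Q	Unknown, Dorset	Dorset	this panel	no
BMP15	W154Δ17	Fecundity, Rasa Aragonesa, FecX^R	Rasa Aragonesa	literature	yes
BMP15	Q239stop	Fecundity, Galway, FecX^G	Belclare, Cambridge	literature	yes
BMP15	L252P	Unknown, Dorper	Dorper	this panel	no
BMP15	Q291stop	Fecundity, Hanna, FecX^H	Romney	literature	yes
BMP15	V299D	Fecundity, Inverdale, FecX^I	Romney	literature	yes
BMP15	T317I	Fecundity, Grivette, FecX^GR	Grivette	literature	yes
BMP15	C321Y	Fecundity, Lacaune, FecX^L	Lacaune	literature	yes
BMP15	N337H	Fecundity, Olkuska, FecX^O	Olkuska	literature	yes
BMP15	S367I	Fecundity, Belclare, FecX^B	Belclare	literature	yes
BMPR1B	M64I	Unknown, Katahdin	Katahdin	this panel	no
BMPR1B	Q249R	Fecundity, Booroola, FecB^B	Booroola Merino and others	literature	yes
BMPR1B	T345N	Unknown, Romanov	Romanov	this panel	no
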