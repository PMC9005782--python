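# three-letter component codes treated as cofactors (ionic, non-ionic,
# and single-atom components: metals, non-metals, noble gases).
# Editable: extend freely; comp_id <TAB> human-readable label
HEM	protoporphyrin IX / heme
HEC	heme c
FAD	flavin adenine dinucleotide
FMN	flavin mononucleotide
NAD	nicotinamide adenine dinucleotide
NAI	NADH
NAP	NADP
NDP	NADPH
SAM	S-adenosylmethionine
SAH	S-adenosylhomocysteine
PLP	pyridoxal 5'-phosphate
TPP	thiamine diphosphate
TDP	thiamine diphosphate
COA	coenzyme A
ACO	acetyl coenzyme A
BTN	biotin
H4B	tetrahydrobiopterin
MQ7	menaquinone-7
PQQ	pyrroloquinoline quinone
F43	coenzyme F430
B12	cobalamin
GSH	glutathione
ZN	zinc ion
MG	magnesium ion
MN	manganese ion
FE	iron (III) ion
FE2	iron (II) ion
CA	calcium ion
CU	copper (II) ion
CU1	copper (I) ion
NI	nickel ion
CO	cobalt ion
MO	molybdenum ion
W	tungsten ion
K	potassium ion
NA	sodium ion
SE	selenium
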