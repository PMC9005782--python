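# three-letter component codes of common crystallisation additives.
# A component in this list is called an artefact only if it also fails
# the 30% similarity bar against every cognate component and cofactor.
GOL	glycerol
EDO	ethylene glycol
PEG	di(hydroxyethyl)ether
PGE	triethylene glycol
1PE	pentaethylene glycol
MPD	2-methyl-2,4-pentanediol
SO4	sulfate ion
PO4	phosphate ion
ACT	acetate ion
ACY	acetic acid
FMT	formic acid
CIT	citric acid
TRS	tris buffer
EPE	HEPES buffer
MES	MES buffer
IMD	imidazole
DMS	dimethyl sulfoxide
BME	beta-mercaptoethanol
DTT	dithiothreitol
NO3	nitrate ion
CL	chloride ion
BR	bromide ion
IOD	iodide ion
CS	cesium ion
HOH	water
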