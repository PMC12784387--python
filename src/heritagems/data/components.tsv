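# Named chemical components used as parents for candidate-ion generation.
# Columns: name, abbreviation, class, formula, families (semicolon-separated).
# Classes: fatty_acid, dicarboxylic_acid, degradation_acid, backbone,
#   resin_acid_abietane, triterpenoid_dammarane, triterpenoid_pentacyclic,
#   sesquiterpene, wax_alkane,
#   wax_alcohol, wax_diol, sterol, pah_marker.
# Families: colophony, linseed_oil, egg_yolk, dammar, beeswax, pine_tar.
name	abbreviation	class	formula	families
glycerol	Gro	backbone	C3H8O3	linseed_oil;egg_yolk
myristic acid	M	fatty_acid	C14H28O2	linseed_oil;egg_yolk;beeswax
palmitoleic acid	Po	fatty_acid	C16H30O2	linseed_oil;egg_yolk
palmitic acid	P	fatty_acid	C16H32O2	linseed_oil;egg_yolk;beeswax
linolenic acid	Ln	fatty_acid	C18H30O2	linseed_oil;egg_yolk
linoleic acid	L	fatty_acid	C18H32O2	linseed_oil;egg_yolk
oleic acid	O	fatty_acid	C18H34O2	linseed_oil;egg_yolk;beeswax
stearic acid	S	fatty_acid	C18H36O2	linseed_oil;egg_yolk
eicosenoic acid	Eic	fatty_acid	C20H38O2	linseed_oil;egg_yolk
arachidic acid	Ar	fatty_acid	C20H40O2	linseed_oil;egg_yolk
behenic acid	Be	fatty_acid	C22H44O2	linseed_oil;egg_yolk
pimelic acid	Pi	dicarboxylic_acid	C7H12O4	linseed_oil
suberic acid	Su	dicarboxylic_acid	C8H14O4	linseed_oil
azelaic acid	Az	dicarboxylic_acid	C9H16O4	linseed_oil
sebacic acid	Se	dicarboxylic_acid	C10H18O4	linseed_oil
octanoic acid	C8:0	degradation_acid	C8H16O2	linseed_oil
8-oxooctanoic acid	8-OOA	degradation_acid	C8H14O3	linseed_oil
nonanoic acid	C9:0	degradation_acid	C9H18O2	linseed_oil
2-nonenoic acid	C9:1	degradation_acid	C9H16O2	linseed_oil
9-oxononanoic acid	9-ONA	degradation_acid	C9H16O3	linseed_oil
decadienoic acid	C10:2	degradation_acid	C10H16O2	linseed_oil
abietic acid	AA	resin_acid_abietane	C20H30O2	colophony;pine_tar
dehydroabietic acid	DHA	resin_acid_abietane	C20H28O2	colophony;pine_tar
didehydroabietic acid	dDHA	resin_acid_abietane	C20H26O2	colophony;pine_tar
7-oxodehydroabietic acid	7-oxo-DHA	resin_acid_abietane	C20H26O3	colophony;pine_tar
15-hydroxydehydroabietic acid	15-OH-DHA	resin_acid_abietane	C20H28O3	colophony;pine_tar
15-hydroxy-7-oxodehydroabietic acid	15-OH-7-oxo-DHA	resin_acid_abietane	C20H26O4	colophony;pine_tar
dammaradienol	DDol	triterpenoid_dammarane	C30H50O	dammar
dammaradienone	DDon	triterpenoid_dammarane	C30H48O	dammar
hydroxydammarenone	HDon	triterpenoid_dammarane	C30H50O2	dammar
dammarenolic acid	DLA	triterpenoid_dammarane	C30H50O3	dammar
oleanonic/ursonic acid	OUA	triterpenoid_pentacyclic	C30H46O3	dammar
nor-amyrone	nAm	triterpenoid_pentacyclic	C29H46O	dammar
cadinene	Cad	sesquiterpene	C15H24	dammar
pentacosane	PCs	wax_alkane	C25H52	beeswax
heptacosane	HCs	wax_alkane	C27H56	beeswax
triacontanol	TrOH	wax_alcohol	C30H62O	beeswax
triacontane-1,30-diol	TrDiol	wax_diol	C30H62O2	beeswax
cholesterol	Chol	sterol	C27H46O	egg_yolk
3-hydroxycholest-5-en-7-one	ChOx	sterol	C27H44O2	egg_yolk
retene	Ret	pah_marker	C18H18	pine_tar
simonellite	Sim	pah_marker	C19H24	pine_tar
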