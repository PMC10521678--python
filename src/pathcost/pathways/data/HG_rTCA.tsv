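% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
Cit	citrate	internal	1e-06	0.01	6	18
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
FormylCoA	formyl-CoA	internal	1e-06	0.01	1	2
Fum	fumarate	internal	1e-06	0.01	4	12
HG	2-hydroxyglutarate	internal	1e-06	0.01	5	18
HGCoA	2-hydroxyglutaryl-CoA	internal	1e-06	0.01	5	18
Isocit	isocitrate	internal	1e-06	0.01	6	18
MQ	menaquinone	fixed-cofactor	1e-06	0.01	0	0
MQH2	menaquinol	fixed-cofactor	1e-06	0.01	0	2
Mal	malate	internal	1e-06	0.01	4	12
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	internal	1e-06	0.01	4	10
OG	2-oxoglutarate	internal	1e-06	0.01	5	16
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
SSA	succinate semialdehyde	internal	1e-06	0.01	4	16
Succ	succinate	internal	1e-06	0.01	4	14
SuccCoA	succinyl-CoA	internal	1e-06	0.01	4	14
formate	formate	exchanged	1e-06	0.01	1	2
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
fcl	formate + ATP + CoA <=> FormylCoA + ADP + Pi	1000	1	100	0
scr_hg	SuccCoA + NADPH <=> SSA + CoA + NADP	1000	1	100	0
hacl	SSA + FormylCoA <=> HGCoA	1000	1	100	0
hgct	HGCoA + Succ <=> HG + SuccCoA	1000	1	100	0
lmt	HG + OAA <=> OG + Mal	1000	1	100	0
idh	OG + CO2 + NADPH <=> Isocit + NADP	1000	1	100	0
acn	Isocit <=> Cit	1000	1	100	0
acl	Cit + ATP + CoA <=> OAA + AcCoA + ADP + Pi	1000	1	100	0
fum_hg	Mal <=> Fum	1000	1	100	0
frd_hg	Fum + MQH2 <=> Succ + MQ	1000	1	100	2
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
HG_rTCA	AcCoA	1
!!SBtab TableType='Flux'
!ReactionID	!Value
fcl	1
scr_hg	1
hacl	1
hgct	1
lmt	1
idh	1
acn	1
acl	1
fum_hg	1
frd_hg	1
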