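% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
2PG	2-phosphoglycerate	internal	1e-06	0.01	3	10
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
AMP	AMP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
Glycerate	glycerate	internal	1e-06	0.01	3	10
Glyox	glyoxylate	internal	1e-06	0.01	2	4
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
Mal	malate	internal	1e-06	0.01	4	12
MalylCoA	malyl-CoA	internal	1e-06	0.01	4	12
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	internal	1e-06	0.01	4	10
PEP	phosphoenolpyruvate	internal	1e-06	0.01	3	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
Pyr	pyruvate	exchanged	1e-06	0.01	3	10
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
peps_g	Pyr + ATP <=> PEP + AMP + Pi	1000	1	100	0
pepc_g	PEP + HCO3 <=> OAA + Pi	1000	1	100	0
mdh_m	OAA + NADH <=> Mal + NAD	1000	1	100	0
mtk	Mal + ATP + CoA <=> MalylCoA + ADP + Pi	1000	1	100	0
mcl	MalylCoA <=> AcCoA + Glyox	1000	1	100	0
gcl_gdh_m	2 Glyox + NADH <=> Glycerate + NAD + CO2	1000	1	100	0
gk	Glycerate + ATP <=> 2PG + ADP	1000	1	100	0
eno	2PG <=> PEP	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
MCG_glycerate	AcCoA	2
!!SBtab TableType='Flux'
!ReactionID	!Value
peps_g	1
pepc_g	2
mdh_m	2
mtk	2
mcl	2
gcl_gdh_m	1
gk	1
eno	1
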