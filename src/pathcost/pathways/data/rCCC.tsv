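% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
4HB	4-hydroxybutyrate	internal	1e-06	0.01	4	18
4HBCoA	4-hydroxybutyryl-CoA	internal	1e-06	0.01	4	18
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
CitMalCoA	citramalyl-CoA	internal	1e-06	0.01	5	18
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
CrotCoA	crotonyl-CoA	internal	1e-06	0.01	4	18
EMCoA	ethylmalonyl-CoA	internal	1e-06	0.01	5	20
Fum	fumarate	internal	1e-06	0.01	4	12
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
MQ	menaquinone	fixed-cofactor	1e-06	0.01	0	0
MQH2	menaquinol	fixed-cofactor	1e-06	0.01	0	2
Mal	malate	internal	1e-06	0.01	4	12
MesacCoA	mesaconyl-C1-CoA	internal	1e-06	0.01	5	18
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	internal	1e-06	0.01	4	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
Pyr	pyruvate	internal	1e-06	0.01	3	10
SSA	succinate semialdehyde	internal	1e-06	0.01	4	16
Succ	succinate	internal	1e-06	0.01	4	14
SuccCoA	succinyl-CoA	internal	1e-06	0.01	4	14
UQ	ubiquinone	fixed-cofactor	1e-06	0.01	0	0
UQH2	ubiquinol	fixed-cofactor	1e-06	0.01	0	2
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
pyc	Pyr + HCO3 + ATP <=> OAA + ADP + Pi	1000	1	100	0
mdh	OAA + NADH <=> Mal + NAD	1000	1	100	0
fum	Mal <=> Fum	1000	1	100	0
frd	Fum + MQH2 <=> Succ + MQ	1000	1	100	2
scs	Succ + ATP + CoA <=> SuccCoA + ADP + Pi	1000	1	100	0
scr	SuccCoA + NADPH <=> SSA + CoA + NADP	1000	1	100	0
ssar	SSA + NADPH <=> 4HB + NADP	1000	1	100	0
hbl	4HB + ATP + CoA <=> 4HBCoA + ADP + Pi	1000	1	100	0
hbd	4HBCoA <=> CrotCoA	1000	1	100	0
ccr	CrotCoA + CO2 + NADPH <=> EMCoA + NADP	1000	1	100	0
emm	EMCoA + UQ <=> MesacCoA + UQH2	1000	1	100	0
mch	MesacCoA <=> CitMalCoA	1000	1	100	0
ccl	CitMalCoA <=> AcCoA + Pyr	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
rCCC	AcCoA	1
!!SBtab TableType='Flux'
!ReactionID	!Value
pyc	1
mdh	1
fum	1
frd	1
scs	1
scr	1
ssar	1
hbl	1
hbd	1
ccr	1
emm	1
mch	1
ccl	1
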