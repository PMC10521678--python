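% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
3HP	3-hydroxypropionate	internal	1e-06	0.01	3	12
3HPCoA	3-hydroxypropionyl-CoA	internal	1e-06	0.01	3	12
4HB	4-hydroxybutyrate	internal	1e-06	0.01	4	18
4HBCoA	4-hydroxybutyryl-CoA	internal	1e-06	0.01	4	18
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
AMP	AMP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
AcAcCoA	acetoacetyl-CoA	internal	1e-06	0.01	4	16
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
CrotCoA	crotonyl-CoA	internal	1e-06	0.01	4	18
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
MMCoA	methylmalonyl-CoA	internal	1e-06	0.01	4	14
MalonylCoA	malonyl-CoA	internal	1e-06	0.01	3	8
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
PPi	pyrophosphate	fixed-cofactor	1e-06	0.01	0	0
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
PropCoA	propionyl-CoA	internal	1e-06	0.01	3	14
SuccCoA	succinyl-CoA	internal	1e-06	0.01	4	14
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
acc	AcCoA + HCO3 + ATP <=> MalonylCoA + ADP + Pi	1000	1	100	0
mcr	MalonylCoA + 2 NADPH <=> 3HP + 2 NADP + CoA	1000	1	100	0
hpcs	3HP + ATP + CoA <=> 3HPCoA + AMP + PPi	1000	1	100	0
hpcd	3HPCoA + NADPH <=> PropCoA + NADP	1000	1	100	0
pcc	PropCoA + HCO3 + ATP <=> MMCoA + ADP + Pi	1000	1	100	0
mcm	MMCoA <=> SuccCoA	1000	1	100	0
scr4	SuccCoA + 2 NADPH <=> 4HB + 2 NADP + CoA	1000	1	100	0
hbcs	4HB + ATP + CoA <=> 4HBCoA + AMP + PPi	1000	1	100	0
hbcd	4HBCoA <=> CrotCoA	1000	1	100	0
crt	CrotCoA + NAD <=> AcAcCoA + NADH	1000	1	100	0
thl	AcAcCoA + CoA <=> 2 AcCoA	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
HP4HB_cren	AcCoA	1
!!SBtab TableType='Flux'
!ReactionID	!Value
acc	1
mcr	1
hpcs	1
hpcd	1
pcc	1
mcm	1
scr4	1
hbcs	1
hbcd	1
crt	1
thl	1
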