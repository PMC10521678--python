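% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
AMP	AMP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
CO2	carbon dioxide	internal	1e-06	0.01	1	0
GAP	glyceraldehyde-3-phosphate	exchanged	1e-06	0.01	3	12
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
Mal	malate	internal	1e-06	0.01	4	12
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	internal	1e-06	0.01	4	10
PEP	phosphoenolpyruvate	internal	1e-06	0.01	3	10
PGA	3-phosphoglycerate	internal	1e-06	0.01	3	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
Pyr	pyruvate	internal	1e-06	0.01	3	10
RuBP	ribulose-1,5-bisphosphate	internal	1e-06	0.01	5	20
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
rbc	RuBP + CO2 <=> 2 PGA	1000	1	100	0
pgk_gapdh	PGA + ATP + NADPH <=> GAP + ADP + Pi + NADP	1000	1	100	0
regen	5 GAP + 3 ATP <=> 3 RuBP + 3 ADP + 2 Pi	1000	1	100	0
peps	Pyr + ATP <=> PEP + AMP + Pi	1000	1	100	0
pepc	PEP + HCO3 <=> OAA + Pi	1000	1	100	0
mdh_c4	OAA + NADPH <=> Mal + NADP	1000	1	100	0
me_c4	Mal + NADP <=> Pyr + CO2 + NADPH	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
C4_CBB_PEPS	GAP	1
!!SBtab TableType='Flux'
!ReactionID	!Value
rbc	3
pgk_gapdh	6
regen	1
peps	3
pepc	3
mdh_c4	3
me_c4	3
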