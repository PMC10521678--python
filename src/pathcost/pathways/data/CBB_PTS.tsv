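% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
GAP	glyceraldehyde-3-phosphate	exchanged	1e-06	0.01	3	12
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
PGA	3-phosphoglycerate	internal	1e-06	0.01	3	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
RuBP	ribulose-1,5-bisphosphate	internal	1e-06	0.01	5	20
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
rbc	RuBP + CO2 <=> 2 PGA	1000	1	100	0
pgk_gapdh	PGA + ATP + NADPH <=> GAP + ADP + Pi + NADP	1000	1	100	0
regen_pts	5 GAP + ATP <=> 3 RuBP + ADP	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
CBB_PTS	GAP	1
!!SBtab TableType='Flux'
!ReactionID	!Value
rbc	3
pgk_gapdh	6
regen_pts	1
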