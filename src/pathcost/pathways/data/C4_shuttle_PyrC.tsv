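% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
Mal	malate	internal	1e-06	0.01	4	12
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	internal	1e-06	0.01	4	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
Pyr	pyruvate	internal	1e-06	0.01	3	10
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
pyc_c4	Pyr + HCO3 + ATP <=> OAA + ADP + Pi	1000	1	100	0
mdh_c4	OAA + NADPH <=> Mal + NADP	1000	1	100	0
me_c4	Mal + NADP <=> Pyr + CO2 + NADPH	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
C4_shuttle_PyrC	CO2	1
!!SBtab TableType='Flux'
!ReactionID	!Value
pyc_c4	1
mdh_c4	1
me_c4	1
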