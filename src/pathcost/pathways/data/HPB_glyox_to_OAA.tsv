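% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
Glyox	glyoxylate	exchanged	1e-06	0.01	2	4
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	exchanged	1e-06	0.01	4	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
hpb	Glyox + 3 NADPH + 2 HCO3 + ATP <=> OAA + 3 NADP + ADP + Pi	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
HPB_glyox_to_OAA	OAA	1
!!SBtab TableType='Flux'
!ReactionID	!Value
hpb	1
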