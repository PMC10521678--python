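% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
Glyox	glyoxylate	exchanged	1e-06	0.01	2	4
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	exchanged	1e-06	0.01	4	10
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
bhac	2 Glyox + NADH <=> OAA + NAD	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
bOHAsp_module	OAA	1
!!SBtab TableType='Flux'
!ReactionID	!Value
bhac	1
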