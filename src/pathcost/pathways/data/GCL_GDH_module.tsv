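% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
Glycerate	glycerate	exchanged	1e-06	0.01	3	10
Glyox	glyoxylate	exchanged	1e-06	0.01	2	4
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
gcl_gdh	2 Glyox + NADH <=> Glycerate + NAD + CO2	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
GCL_GDH_module	Glycerate	1
!!SBtab TableType='Flux'
!ReactionID	!Value
gcl_gdh	1
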