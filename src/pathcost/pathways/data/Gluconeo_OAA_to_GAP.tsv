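% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
GAP	glyceraldehyde-3-phosphate	exchanged	1e-06	0.01	3	12
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	exchanged	1e-06	0.01	4	10
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
gng	OAA + 2 ATP + NADH <=> GAP + 2 ADP + Pi + NAD + CO2	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
Gluconeo_OAA_to_GAP	GAP	1
!!SBtab TableType='Flux'
!ReactionID	!Value
gng	1
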