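% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
Glyox	glyoxylate	exchanged	1e-06	0.01	2	4
MQ	menaquinone	fixed-cofactor	1e-06	0.01	0	0
MQH2	menaquinol	fixed-cofactor	1e-06	0.01	0	2
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
rgs	Glyox + ATP + MQH2 + NADH + CoA <=> AcCoA + ADP + Pi + MQ + NAD	1000	1	100	2
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
RevGlyoxShunt	AcCoA	1
!!SBtab TableType='Flux'
!ReactionID	!Value
rgs	1
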