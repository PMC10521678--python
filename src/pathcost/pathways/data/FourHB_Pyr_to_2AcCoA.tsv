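% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
ADP	ADP	fixed-cofactor	1e-06	0.01	0	0
ATP	ATP	fixed-cofactor	1e-06	0.01	0	0
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
MQ	menaquinone	fixed-cofactor	1e-06	0.01	0	0
MQH2	menaquinol	fixed-cofactor	1e-06	0.01	0	2
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
Pi	phosphate	fixed-cofactor	1e-06	0.01	0	0
Pyr	pyruvate	exchanged	1e-06	0.01	3	10
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
fhb	Pyr + 2 CoA + 3 ATP + HCO3 + MQH2 + 2 NADPH <=> 2 AcCoA + 3 ADP + 3 Pi + MQ + 2 NADP	1000	1	100	2
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
FourHB_Pyr_to_2AcCoA	AcCoA	2
!!SBtab TableType='Flux'
!ReactionID	!Value
fhb	1
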