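% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CO2	carbon dioxide	exchanged	1e-06	0.01	1	0
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
MQ	menaquinone	fixed-cofactor	1e-06	0.01	0	0
MQH2	menaquinol	fixed-cofactor	1e-06	0.01	0	2
NAD	NAD+	fixed-cofactor	1e-06	0.01	0	0
NADH	NADH	fixed-cofactor	1e-06	0.01	0	2
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
OAA	oxaloacetate	exchanged	1e-06	0.01	4	10
UQ	ubiquinone	fixed-cofactor	1e-06	0.01	0	0
UQH2	ubiquinol	fixed-cofactor	1e-06	0.01	0	2
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
emc	2 AcCoA + 2 NADPH + 1/2 NAD + UQ + MQ + HCO3 + CO2 <=> 3/2 OAA + 2 NADP + 1/2 NADH + UQH2 + MQH2 + 2 CoA	1000	1	100	-2
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
EMC_module	OAA	1.5
!!SBtab TableType='Flux'
!ReactionID	!Value
emc	1
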