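% Synthetic placeholder Keq/enzyme masses; stoichiometries and fluxes follow the published pathway definitions.
!!SBtab TableType='Compound'
!ID	!Name	!Role	!LowerBoundM	!UpperBoundM	!CarbonCount	!ElectronCount
3HBCoA	3-hydroxybutyryl-CoA	internal	1e-06	0.01	4	18
AcAcCoA	acetoacetyl-CoA	internal	1e-06	0.01	4	16
AcCoA	acetyl-CoA	exchanged	1e-06	0.01	2	8
CitMalCoA	citramalyl-CoA	internal	1e-06	0.01	5	18
CoA	coenzyme A	fixed-cofactor	1e-06	0.01	0	0
CrotCoA	crotonyl-CoA	internal	1e-06	0.01	4	18
EMCoA	ethylmalonyl-CoA	internal	1e-06	0.01	5	20
HCO3	bicarbonate	exchanged	1e-06	0.01	1	0
MesacCoA	mesaconyl-C1-CoA	internal	1e-06	0.01	5	18
NADP	NADP+	fixed-cofactor	1e-06	0.01	0	0
NADPH	NADPH	fixed-cofactor	1e-06	0.01	0	2
Pyr	pyruvate	exchanged	1e-06	0.01	3	10
UQ	ubiquinone	fixed-cofactor	1e-06	0.01	0	0
UQH2	ubiquinol	fixed-cofactor	1e-06	0.01	0	2
!!SBtab TableType='Reaction'
!ID	!ReactionFormula	!Keq	!KeqGSD	!EnzymeMassKDa	!TransportedProtons
thl_r	2 AcCoA <=> AcAcCoA + CoA	1000	1	100	0
hbdh	AcAcCoA + NADPH <=> 3HBCoA + NADP	1000	1	100	0
crt_r	3HBCoA <=> CrotCoA	1000	1	100	0
ccr_r	CrotCoA + HCO3 + NADPH <=> EMCoA + NADP	1000	1	100	0
emm_r	EMCoA + UQ <=> MesacCoA + UQH2	1000	1	100	0
mch_r	MesacCoA <=> CitMalCoA	1000	1	100	0
ccl_r	CitMalCoA <=> AcCoA + Pyr	1000	1	100	0
!!SBtab TableType='Pathway'
!Name	!Product	!ProductRate
rCC_AcCoA_to_Pyr	Pyr	1
!!SBtab TableType='Flux'
!ReactionID	!Value
thl_r	1
hbdh	1
crt_r	1
ccr_r	1
emm_r	1
mch_r	1
ccl_r	1
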