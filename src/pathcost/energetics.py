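"""ATP-equivalent accounting and product–substrate yields.

A pathway's net stoichiometry is converted into a projected ATP cost by
valuing cofactor turnover in ATP equivalents under optimal aerobic
respiration: NADH -> 2.5 ATP, quinol (UQH2/MQH2/FADH2) -> 1.5 ATP,
NADPH -> 2.75 ATP (one NADH plus 0.25 ATP for the membrane transhydrogenase
at H+/ATP = 4), AMP-forming ATP consumption counts twice.  Produced reduced
cofactors credit the ledger at the same values.

Yields on an electron/carbon donor (formate, methanol, H2) convert the
total ATP-equivalent demand into donor equivalents via the NADH each donor
delivers (plus any directly donor-sourced ATP, e.g. PQQ-dependent methanol
oxidation), and add the donor molecules incorporated as carbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CofactorEquivalence",
    "DonorSpec",
    "atp_equivalent_cost",
    "atp_count",
    "product_substrate_yield",
    "COFACTOR_SPECIES",
]

#: Species treated as cofactors by the ledger (everything else in a net
#: stoichiometry must be declared as a carbon substrate/product).
COFACTOR_SPECIES = {
    "ATP", "ADP", "AMP", "Pi", "PPi",
    "NADH", "NAD", "NADPH", "NADP",
    "UQ", "UQH2", "MQ", "MQH2", "FAD", "FADH2",
    "CoA", "THF",
}


@dataclass(frozen=True)
class CofactorEquivalence:
    """ATP values of cofactor turnover under optimal aerobic respiration."""

    atp_per_nadh: float = 2.5
    atp_per_quinol: float = 1.5
    atp_per_nadph_extra: float = 0.25
    atp_per_amp_regeneration: float = 2.0
    atp_per_pqq_methanol: float = 1.0
    h_per_atp: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "atp_per_nadh", "atp_per_quinol", "atp_per_nadph_extra",
            "atp_per_amp_regeneration", "atp_per_pqq_methanol", "h_per_atp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def atp_per_nadph(self) -> float:
        """Full ATP value of NADPH: one NADH plus the transhydrogenase cost."""
        return self.atp_per_nadh + self.atp_per_nadph_extra

    def species_values(self) -> dict[str, float]:
        """ATP-equivalent value per cofactor species.

        Values are chosen so that the cost of a net turnover map is
        ``sum_c value(c) * (-net(c))``: consuming ATP (net -1) costs 1,
        ATP -> AMP costs ``atp_per_amp_regeneration`` (AMP valued at
        1 - 2 = -1), consuming NADH costs 2.5, producing quinol credits 1.5.
        """
        return {
            "ATP": 1.0,
            "ADP": 0.0,
            "AMP": 1.0 - self.atp_per_amp_regeneration,
            "Pi": 0.0,
            "PPi": 0.0,
            "NADH": self.atp_per_nadh,
            "NAD": 0.0,
            "NADPH": self.atp_per_nadph,
            "NADP": 0.0,
            "UQH2": self.atp_per_quinol,
            "UQ": 0.0,
            "MQH2": self.atp_per_quinol,
            "MQ": 0.0,
            "FADH2": self.atp_per_quinol,
            "FAD": 0.0,
            "CoA": 0.0,
            "THF": 0.0,
        }


@dataclass(frozen=True)
class DonorSpec:
    """An electron (and possibly carbon) donor regenerating NADH.

    ``nadh_per_donor`` is the NADH delivered per donor molecule fully
    oxidized; ``atp_per_donor`` any ATP generated directly (PQQ-dependent
    methanol oxidation); ``carbons_per_donor`` the carbon atoms available
    for incorporation per donor molecule.
    """

    donor: str
    nadh_per_donor: float
    atp_per_donor: float = 0.0
    carbons_per_donor: int = 0

    def __post_init__(self) -> None:
        if self.nadh_per_donor < 0:
            raise ValueError("nadh_per_donor must be >= 0")


#: Default donors.  Formate: one NADH via formate dehydrogenase.  Methanol,
#: NAD route: 3 NADH per methanol fully oxidized to CO2.  Methanol, PQQ
#: route: 1 ATP from the PQQ dehydrogenase plus 2 NADH downstream.  H2: one
#: NADH via a soluble hydrogenase.
DONORS = {
    "formate": DonorSpec("formate", nadh_per_donor=1.0, carbons_per_donor=1),
    "methanol_nad": DonorSpec("methanol", nadh_per_donor=3.0, carbons_per_donor=1),
    "methanol_pqq": DonorSpec(
        "methanol", nadh_per_donor=2.0, atp_per_donor=1.0, carbons_per_donor=1
    ),
    "H2": DonorSpec("H2", nadh_per_donor=1.0, carbons_per_donor=0),
}


def _split_net(
    net: dict[str, float], eq: CofactorEquivalence, carbon_species: set[str]
) -> tuple[dict[str, float], dict[str, float]]:
    values = eq.species_values()
    cofactors, carbons = {}, {}
    unknown = []
    for mid, coeff in net.items():
        if mid in values:
            cofactors[mid] = coeff
        elif mid in carbon_species:
            carbons[mid] = coeff
        else:
            unknown.append(mid)
    if unknown:
        raise ValueError(
            "unrecognized species in net stoichiometry (declare as carbon "
            f"substrate/product or add to the cofactor ledger): {sorted(unknown)}"
        )
    return cofactors, carbons


def atp_equivalent_cost(
    net: dict[str, float],
    eq: CofactorEquivalence | None = None,
    carbon_species: set[str] | None = None,
) -> float:
    """Projected ATP cost of a net stoichiometry, in ATP equivalents.

    Consumed cofactors are charged at their ATP values, produced reduced
    cofactors credit the ledger.  ``carbon_species`` lists the species to
    ignore (the pathway's substrates/products); anything neither listed
    there nor a known cofactor raises an error.
    """
    eq = eq or CofactorEquivalence()
    carbon_species = carbon_species if carbon_species is not None else _guess_carbons(net)
    cofactors, _ = _split_net(net, eq, carbon_species)
    values = eq.species_values()
    return -sum(values[mid] * coeff for mid, coeff in cofactors.items())


def atp_count(net: dict[str, float]) -> float:
    """Direct ATP-hydrolysis count: ATP -> ADP as 1, ATP -> AMP as 2.

    Redox cofactors are ignored.  Counted from the phosphorylation state
    of the adenine nucleotides in the net stoichiometry.
    """
    return net.get("ADP", 0.0) + 2.0 * net.get("AMP", 0.0)


def _guess_carbons(net: dict[str, float]) -> set[str]:
    return {mid for mid in net if mid not in COFACTOR_SPECIES}


def product_substrate_yield(
    net: dict[str, float],
    donor: DonorSpec,
    eq: CofactorEquivalence | None = None,
    carbon_species: set[str] | None = None,
) -> float:
    """Mol product per mol donor, all demands covered by the donor.

    The net stoichiometry must be normalized to +1 product.  Total donor
    demand is the sum of donor molecules incorporated as carbon and the
    donors oxidized to cover the ATP-equivalent cost of the remaining
    cofactor turnover:

        demand = carbon_demand + cost / (nadh_per_donor * atp_per_nadh
                                         + atp_per_donor)

    Yield is 1 / demand.
    """
    eq = eq or CofactorEquivalence()
    carbon_species = carbon_species if carbon_species is not None else _guess_carbons(net)
    cofactors, carbons = _split_net(net, eq, carbon_species)
    values = eq.species_values()
    cost = -sum(values[mid] * coeff for mid, coeff in cofactors.items())

    carbon_demand = -carbons.get(donor.donor, 0.0)
    if carbon_demand < 0:
        raise ValueError(f"pathway produces its own donor {donor.donor!r}")

    atp_per_donor_total = donor.nadh_per_donor * eq.atp_per_nadh + donor.atp_per_donor
    if atp_per_donor_total <= 0:
        raise ValueError(
            f"donor {donor.donor!r} supplies no usable energy (nadh_per_donor and "
            "atp_per_donor both zero)"
        )
    energy_demand = cost / atp_per_donor_total
    total = carbon_demand + energy_demand
    if total <= 0:
        raise ValueError(
            "pathway has no net donor demand; yield on this donor is unbounded"
        )
    return 1.0 / total
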