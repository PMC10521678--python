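"""Domain types for metabolic networks and flux distributions.

A :class:`NetworkModel` is an ordered collection of metabolites and reactions
with signed rational stoichiometries (products positive).  Concentrations are
molar everywhere; equilibrium constants are transformed constants w.r.t. a
1 M standard state at the model's implicit pH.  Water and protons are omitted
from stoichiometries — their effect is assumed folded into the transformed
Keq inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "NetworkModel",
    "FluxDistribution",
    "ParameterRecord",
    "FluxValidationReport",
    "stoichiometric_matrix",
    "net_stoichiometry",
    "validate_flux",
]

#: Relative tolerance for the internal-metabolite steady-state check.
STEADY_STATE_RTOL = 1e-9

ROLES = ("internal", "exchanged", "fixed-cofactor")
QUANTITY_TYPES = ("kcat_forward", "kcat_backward", "km", "keq")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species of the network.

    Parameters
    ----------
    id:
        Short unique token, e.g. ``"GAP"``.
    name:
        Free-text name.
    role:
        ``"internal"`` (must balance at steady state), ``"exchanged"``
        (pathway substrate/product or freely supplied cofactor) or
        ``"fixed-cofactor"`` (concentration clamped during optimization).
    default_bounds:
        Allowed concentration interval in molar, both ends > 0.
    carbon_count, electron_count:
        Optional bookkeeping used for carbon/electron balance checks
        (electrons counted relative to CO2/H2O/phosphate; 2 e- per
        NAD(P)H or quinol).
    """

    id: str
    name: str = ""
    role: str = "internal"
    default_bounds: tuple[float, float] = (1e-6, 1e-2)
    carbon_count: int = 0
    electron_count: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.id}")
        lb, ub = self.default_bounds
        if not (0 < lb <= ub):
            raise ValueError(
                f"metabolite {self.id}: bounds must satisfy 0 < lower <= upper, got ({lb}, {ub})"
            )


@dataclass(frozen=True)
class Reaction:
    """A reversible enzymatic reaction with signed stoichiometry.

    ``stoichiometry`` maps metabolite id to a signed rational coefficient,
    products positive.  ``keq`` is the equilibrium constant in the written
    direction (dimensionless w.r.t. 1 M); ``z_protons`` is the number of
    protons translocated cytosol -> periplasm per catalytic event (positive
    outward).  ``enzyme_mass`` is the enzyme molecular mass in kDa, i.e.
    mg per umol.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    enzyme_mass: float = 100.0
    z_protons: int = 0
    keq: float = 1.0
    keq_gsd: float = 1.0

    def __post_init__(self) -> None:
        coeffs = dict(self.stoichiometry)
        object.__setattr__(
            self, "stoichiometry", {m: Fraction(c) for m, c in coeffs.items() if c != 0}
        )
        if not any(c < 0 for c in self.stoichiometry.values()) or not any(
            c > 0 for c in self.stoichiometry.values()
        ):
            raise ValueError(
                f"reaction {self.id}: needs at least one substrate and one product"
            )
        if self.enzyme_mass <= 0:
            raise ValueError(f"reaction {self.id}: enzyme_mass must be > 0")
        if self.keq <= 0:
            raise ValueError(f"reaction {self.id}: keq must be > 0")
        if self.keq_gsd < 1:
            raise ValueError(f"reaction {self.id}: keq_gsd must be >= 1")

    @property
    def substrates(self) -> dict[str, Fraction]:
        """Absolute stoichiometric factors of the consumed species."""
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        """Stoichiometric factors of the produced species."""
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass(frozen=True)
class NetworkModel:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ValueError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        rseen: set[str] = set()
        for r in self.reactions:
            if r.id in rseen:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            missing = set(r.stoichiometry) - seen
            if missing:
                raise ValueError(
                    f"reaction {r.id} references unknown metabolite(s): {sorted(missing)}"
                )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


@dataclass(frozen=True)
class FluxDistribution:
    """Nonnegative relative fluxes defining a pathway.

    Reaction orientation encodes direction, so all fluxes are >= 0.
    ``product_rate`` is the net production of ``product`` per unit pathway
    flux (used to convert enzyme cost into a specific activity).
    """

    name: str
    fluxes: Mapping[str, float]
    product: str
    product_rate: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fluxes", dict(self.fluxes))
        if any(v < 0 for v in self.fluxes.values()):
            bad = [k for k, v in self.fluxes.items() if v < 0]
            raise ValueError(f"fluxes must be >= 0 (negative: {bad})")
        if self.product_rate <= 0:
            raise ValueError("product_rate must be > 0")


@dataclass(frozen=True)
class ParameterRecord:
    """One observed kinetic/thermodynamic quantity with geometric uncertainty."""

    reaction_id: str
    quantity: str
    value: float
    gsd: float = 1.0
    compound: str = ""

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITY_TYPES:
            raise ValueError(
                f"unknown quantity type {self.quantity!r}; expected one of {QUANTITY_TYPES}"
            )
        if self.value <= 0:
            raise ValueError(
                f"record ({self.reaction_id}, {self.quantity}, {self.compound}): value must be > 0"
            )
        if self.gsd < 1:
            raise ValueError(
                f"record ({self.reaction_id}, {self.quantity}, {self.compound}): gsd must be >= 1"
            )
        if self.quantity == "km" and not self.compound:
            raise ValueError(f"km record for {self.reaction_id} must carry a compound")


def stoichiometric_matrix(model: NetworkModel) -> np.ndarray:
    """Signed stoichiometric matrix N (n_metabolites x n_reactions)."""
    n_m, n_r = len(model.metabolites), len(model.reactions)
    N = np.zeros((n_m, n_r))
    index = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            N[index[mid], j] = float(coeff)
    return N


@dataclass(frozen=True)
class FluxValidationReport:
    """Steady-state check of a flux distribution; imbalances of internal species."""

    passed: bool
    imbalances: dict[str, float] = field(default_factory=dict)
    tolerance: float = 0.0

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def _net_vector(model: NetworkModel, flux: FluxDistribution) -> dict[str, float]:
    unknown = set(flux.fluxes) - set(model.reaction_ids)
    if unknown:
        raise ValueError(f"flux references unknown reaction(s): {sorted(unknown)}")
    net: dict[str, float] = {}
    for r in model.reactions:
        v = flux.fluxes.get(r.id, 0.0)
        if v == 0:
            continue
        for mid, coeff in r.stoichiometry.items():
            net[mid] = net.get(mid, 0.0) + v * float(coeff)
    return net


def validate_flux(
    model: NetworkModel,
    flux: FluxDistribution,
    exchanged: set[str] | None = None,
) -> FluxValidationReport:
    """Check that all internal metabolites balance under the flux vector.

    ``exchanged`` overrides the roles declared on the model's metabolites;
    species in that set (plus fixed cofactors) are allowed any net
    production.  Passes iff every internal imbalance is below
    ``STEADY_STATE_RTOL`` times the largest flux.
    """
    if exchanged is None:
        exchanged = {m.id for m in model.metabolites if m.role != "internal"}
    net = _net_vector(model, flux)
    vmax = max((abs(v) for v in flux.fluxes.values()), default=0.0)
    tol = STEADY_STATE_RTOL * max(vmax, 1.0)
    imbalances = {
        mid: val
        for mid, val in net.items()
        if mid not in exchanged and abs(val) > tol
    }
    return FluxValidationReport(passed=not imbalances, imbalances=imbalances, tolerance=tol)


def net_stoichiometry(
    model: NetworkModel,
    flux: FluxDistribution,
    exchanged: set[str] | None = None,
) -> dict[str, float]:
    """Net pathway stoichiometry N.v restricted to its nonzero entries.

    Internal metabolites must cancel (steady state); they are dropped from
    the result.  Raises if an internal metabolite carries a net production
    beyond tolerance — the flux vector then does not represent a
    steady-state pathway.
    """
    report = validate_flux(model, flux, exchanged)
    if not report.passed:
        worst = max(report.imbalances, key=lambda m: abs(report.imbalances[m]))
        raise ValueError(
            f"flux {flux.name!r} is not at steady state: internal metabolite "
            f"{worst!r} has net production {report.imbalances[worst]:.3g}"
        )
    if exchanged is None:
        exchanged = {m.id for m in model.metabolites if m.role != "internal"}
    net = _net_vector(model, flux)
    vmax = max((abs(v) for v in flux.fluxes.values()), default=0.0)
    tol = STEADY_STATE_RTOL * max(vmax, 1.0)
    return {mid: val for mid, val in net.items() if mid in exchanged and abs(val) > tol}
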