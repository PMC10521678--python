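"""Thermodynamics: Keq/free-energy conversions, transmembrane Keq adjustment,
reaction driving forces, and the max–min driving-force feasibility check.

Sign conventions
----------------
The driving force of a reaction at log-concentrations x is

    theta = ln Keq - sum_i n_i * x_i

with n_i the signed stoichiometric coefficient (products positive).
theta > 0 iff the reaction is exergonic in its written direction;
DeltaG' = -RT * theta.

For membrane-translocating reactions the equilibrium constant is adjusted as

    Keq' = Keq0 * exp(z * F * dpsi / RT)

where z is the number of protons moved cytosol -> periplasm per catalytic
event (positive outward) and dpsi the transmembrane potential (cytosol
minus periplasm, negative in respiring cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import FluxDistribution, NetworkModel, Reaction

__all__ = [
    "GAS_CONSTANT_KJ",
    "FARADAY_KJ_PER_V",
    "ThermoContext",
    "adjust_keq_for_transport",
    "keq_from_dg",
    "dg_from_keq",
    "driving_force",
    "feasibility_margin",
]

#: Gas constant, kJ / (mol K).
GAS_CONSTANT_KJ = 8.314e-3
#: Faraday constant, kJ / (mol V).
FARADAY_KJ_PER_V = 96.485


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and membrane potential for thermodynamic conversions.

    Defaults: 298.15 K (RT = 2.479 kJ/mol, the eQuilibrator standard) and
    a membrane potential of -150 mV.
    """

    temperature: float = 298.15
    membrane_potential: float = -0.150
    RT: float = field(init=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        object.__setattr__(self, "RT", GAS_CONSTANT_KJ * self.temperature)


def adjust_keq_for_transport(
    keq0: float, z: int, ctx: ThermoContext | None = None
) -> float:
    """Equilibrium constant corrected for proton translocation.

    ``z`` protons moved cytosol -> periplasm (positive outward) against a
    membrane potential ``ctx.membrane_potential`` multiply Keq by
    ``exp(z F dpsi / RT)``.  z = 0 returns ``keq0`` unchanged.
    """
    if keq0 <= 0:
        raise ValueError("keq0 must be > 0")
    ctx = ctx or ThermoContext()
    return keq0 * math.exp(z * FARADAY_KJ_PER_V * ctx.membrane_potential / ctx.RT)


def keq_from_dg(dg: float, ctx: ThermoContext | None = None) -> float:
    """Keq = exp(-DeltaG'/RT), DeltaG' in kJ/mol."""
    ctx = ctx or ThermoContext()
    return math.exp(-dg / ctx.RT)


def dg_from_keq(keq: float, ctx: ThermoContext | None = None) -> float:
    """DeltaG' = -RT ln Keq, in kJ/mol."""
    if keq <= 0:
        raise ValueError("keq must be > 0")
    ctx = ctx or ThermoContext()
    return -ctx.RT * math.log(keq)


def driving_force(reaction: Reaction, log_conc: dict[str, float]) -> float:
    """Dimensionless driving force theta = ln Keq - sum_i n_i x_i.

    ``log_conc`` maps metabolite id to ln(concentration / M) and must cover
    every participant of the reaction.
    """
    missing = set(reaction.stoichiometry) - set(log_conc)
    if missing:
        raise ValueError(
            f"driving_force({reaction.id}): missing log-concentrations for {sorted(missing)}"
        )
    theta = math.log(reaction.keq)
    for mid, coeff in reaction.stoichiometry.items():
        theta -= float(coeff) * log_conc[mid]
    return theta


def feasibility_margin(
    model: NetworkModel,
    flux: FluxDistribution,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Max–min driving force over the concentration box (an LP).

    Solves  max m  s.t.  theta_j(x) >= m for every reaction with positive
    flux and ln(lb_i) <= x_i <= ln(ub_i).  The pathway can carry flux
    forward everywhere iff the optimum m is > 0.

    Concentration ``bounds`` (molar) default to each metabolite's
    ``default_bounds``; fixed species are encoded as lb == ub.
    """
    active = [model.reaction(rid) for rid, v in flux.fluxes.items() if v > 0]
    if not active:
        return math.inf
    mids = sorted({mid for r in active for mid in r.stoichiometry})
    bounds = bounds or {}
    lb = np.empty(len(mids))
    ub = np.empty(len(mids))
    for i, mid in enumerate(mids):
        lo, hi = bounds.get(mid, model.metabolite(mid).default_bounds)
        if not (0 < lo <= hi) or not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"invalid bounds for {mid}: ({lo}, {hi})")
        lb[i], ub[i] = math.log(lo), math.log(hi)

    n = len(mids)
    index = {mid: i for i, mid in enumerate(mids)}
    # variables: (x_1..x_n, m); constraint rows: sum_i n_ij x_i + m <= ln Keq_j
    A = np.zeros((len(active), n + 1))
    b = np.empty(len(active))
    for j, r in enumerate(active):
        for mid, coeff in r.stoichiometry.items():
            A[j, index[mid]] = float(coeff)
        A[j, n] = 1.0
        b[j] = math.log(r.keq)
    c = np.zeros(n + 1)
    c[n] = -1.0  # maximize m
    res = linprog(
        c,
        A_ub=A,
        b_ub=b,
        bounds=[(lb[i], ub[i]) for i in range(n)] + [(None, None)],
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"feasibility LP failed for {flux.name!r}: {res.message}")
    return float(res.x[n])


def mdf_concentrations(
    model: NetworkModel,
    flux: FluxDistribution,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Log-concentrations attaining the max–min driving force.

    Convenience companion to :func:`feasibility_margin`; used as a
    thermodynamically safe starting point for enzyme cost minimization.
    """
    active = [model.reaction(rid) for rid, v in flux.fluxes.items() if v > 0]
    if not active:
        return {}
    mids = sorted({mid for r in active for mid in r.stoichiometry})
    bounds = bounds or {}
    box = []
    for mid in mids:
        lo, hi = bounds.get(mid, model.metabolite(mid).default_bounds)
        box.append((math.log(lo), math.log(hi)))
    n = len(mids)
    index = {mid: i for i, mid in enumerate(mids)}
    A = np.zeros((len(active), n + 1))
    b = np.empty(len(active))
    for j, r in enumerate(active):
        for mid, coeff in r.stoichiometry.items():
            A[j, index[mid]] = float(coeff)
        A[j, n] = 1.0
        b[j] = math.log(r.keq)
    c = np.zeros(n + 1)
    c[n] = -1.0
    res = linprog(c, A_ub=A, b_ub=b, bounds=box + [(None, None)], method="highs")
    if not res.success:
        raise RuntimeError(f"feasibility LP failed for {flux.name!r}: {res.message}")
    return {mid: float(res.x[index[mid]]) for mid in mids}
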