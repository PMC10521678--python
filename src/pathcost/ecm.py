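"""Enzyme Cost Minimization (ECM).

Given a network, balanced kinetics, a flux distribution, concentration
bounds and enzyme masses, find the metabolite concentrations minimizing
the total enzyme mass needed to sustain the fluxes.  Each reaction's
enzyme demand decomposes multiplicatively:

    demand = (v / kcat+) * (1 / eta_rev) * (1 / eta_sat)

* capacity  v / kcat+ — enzyme needed if fully saturated and irreversible;
* reversibility  eta_rev = 1 - exp(-theta) — flux fraction lost to the
  backward reaction at driving force theta;
* saturation  eta_sat — common modular (CM) rate-law occupancy factor

      eta_sat = prod_S s_i^m_i / (prod_S (1+s_i)^m_i + prod_P (1+p_j)^m_j - 1)

  with s = c/Km over substrates and p over products.

The total cost sum_j mass_j * demand_j is convex in the log-concentration
vector, so a local optimizer from a thermodynamically safe interior point
(the max–min driving-force solution) with a few random restarts finds the
global optimum.

Units: concentrations molar, fluxes mM/s, enzyme masses kDa (mg/umol), so
total cost comes out in mg enzyme per mL and the pathway-specific activity
60 * product_rate / cost in umol/min/mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .balancing import BalancedKinetics, PriorSpec, balance_reaction
from .network import FluxDistribution, NetworkModel, ParameterRecord, Reaction
from .thermo import driving_force, feasibility_margin, mdf_concentrations

__all__ = [
    "ConcentrationBounds",
    "EnzymeCostBreakdown",
    "ECMResult",
    "reversibility_factor",
    "saturation_factor",
    "enzyme_demand",
    "minimize_enzyme_cost",
    "specific_activity",
    "monte_carlo_activity",
]

ConcentrationBounds = dict[str, tuple[float, float]]

_PENALTY = 1e30


@dataclass(frozen=True)
class EnzymeCostBreakdown:
    """Per-reaction enzyme demand and its multiplicative decomposition."""

    reaction_id: str
    demand: float
    capacity_term: float
    reversibility_factor: float
    saturation_factor: float


@dataclass(frozen=True)
class ECMResult:
    """Optimal concentrations and enzyme demands for one pathway.

    ``total_enzyme_mass`` is in mg enzyme per mL at unit pathway flux;
    ``specific_activity`` in umol/min per mg total pathway enzyme.
    """

    log_conc: dict[str, float]
    breakdowns: tuple[EnzymeCostBreakdown, ...]
    total_enzyme_mass: float
    specific_activity: float
    converged: bool
    objective_value: float


def reversibility_factor(theta: float) -> float:
    """eta_rev = 1 - exp(-theta), defined for exergonic flux (theta > 0)."""
    if theta <= 0:
        raise ValueError(
            f"thermodynamically infeasible at these concentrations (theta = {theta:.3g})"
        )
    return -math.expm1(-theta)


def saturation_factor(
    reaction: Reaction, conc: dict[str, float], km: dict[str, float]
) -> float:
    """CM rate-law saturation factor in (0, 1].

    Increases with each substrate concentration, decreases with each
    product concentration; 1 in the fully substrate-saturated,
    product-free limit.
    """
    num = 1.0
    denom_s = 1.0
    denom_p = 1.0
    for mid, m in reaction.substrates.items():
        if mid not in km:
            raise ValueError(f"saturation_factor({reaction.id}): missing Km for {mid}")
        if conc[mid] <= 0 or km[mid] <= 0:
            raise ValueError(f"saturation_factor({reaction.id}): non-positive c or Km for {mid}")
        s = conc[mid] / km[mid]
        num *= s ** float(m)
        denom_s *= (1.0 + s) ** float(m)
    for mid, m in reaction.products.items():
        if mid not in km:
            raise ValueError(f"saturation_factor({reaction.id}): missing Km for {mid}")
        p = conc[mid] / km[mid]
        denom_p *= (1.0 + p) ** float(m)
    return num / (denom_s + denom_p - 1.0)


def enzyme_demand(
    reaction: Reaction,
    v: float,
    bk: BalancedKinetics,
    log_conc: dict[str, float],
) -> EnzymeCostBreakdown:
    """Enzyme concentration needed to carry flux ``v`` (mM/s) at ``log_conc``."""
    if v <= 0:
        raise ValueError(f"enzyme_demand({reaction.id}): flux must be > 0")
    theta = driving_force(reaction, log_conc)
    eta_rev = reversibility_factor(theta)
    conc = {mid: math.exp(x) for mid, x in log_conc.items() if mid in reaction.stoichiometry}
    eta_sat = saturation_factor(reaction, conc, bk.km)
    capacity = v / bk.kcat_forward
    return EnzymeCostBreakdown(
        reaction_id=reaction.id,
        demand=capacity / (eta_rev * eta_sat),
        capacity_term=capacity,
        reversibility_factor=eta_rev,
        saturation_factor=eta_sat,
    )


def _resolve_bounds(
    model: NetworkModel, mids: list[str], bounds: ConcentrationBounds | None
) -> dict[str, tuple[float, float]]:
    bounds = bounds or {}
    out = {}
    for mid in mids:
        lo, hi = bounds.get(mid, model.metabolite(mid).default_bounds)
        if not (0 < lo <= hi):
            raise ValueError(f"invalid bounds for {mid}: ({lo}, {hi})")
        out[mid] = (lo, hi)
    return out


def _cost_terms(
    model: NetworkModel,
    flux: FluxDistribution,
    kinetics: dict[str, BalancedKinetics],
) -> list[tuple[Reaction, float, BalancedKinetics]]:
    terms = []
    for rid, v in flux.fluxes.items():
        if v > 0:
            terms.append((model.reaction(rid), v, kinetics[rid]))
    return terms


def ecm_objective(
    x_full: dict[str, float],
    terms: list[tuple[Reaction, float, BalancedKinetics]],
) -> float:
    """Total enzyme mass (mg/mL) at log-concentrations ``x_full``.

    Returns a large penalty growing with the thermodynamic violation when
    any active reaction is infeasible, keeping the optimizer inside the
    feasible region.
    """
    total = 0.0
    violation = 0.0
    for reaction, v, bk in terms:
        theta = driving_force(reaction, x_full)
        if theta <= 1e-12:
            violation += 1.0 - theta
            continue
        bd = enzyme_demand(reaction, v, bk, x_full)
        total += reaction.enzyme_mass * bd.demand
    if violation > 0:
        return _PENALTY * violation
    return total


def minimize_enzyme_cost(
    model: NetworkModel,
    flux: FluxDistribution,
    kinetics: dict[str, BalancedKinetics],
    bounds: ConcentrationBounds | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-9,
) -> ECMResult:
    """Minimize total enzyme mass over the metabolite concentration box.

    Fixed species (lower == upper bound) are substituted out; the
    remaining log-concentrations are optimized from the max–min
    driving-force point plus ``n_restarts`` random interior restarts, and
    the best optimum is kept.  Raises if the box admits no positive
    driving force for some active reaction.
    """
    terms = _cost_terms(model, flux, kinetics)
    if not terms:
        raise ValueError(f"flux {flux.name!r} has no active reactions")
    mids = sorted({mid for r, _, _ in terms for mid in r.stoichiometry})
    box = _resolve_bounds(model, mids, bounds)

    margin = feasibility_margin(model, flux, box)
    if margin <= 0:
        worst = _most_constrained(model, flux, box)
        raise ValueError(
            f"pathway {flux.name!r} is thermodynamically infeasible within the "
            f"concentration box (max-min driving force {margin:.3g}); most "
            f"constrained reaction: {worst}"
        )

    fixed = {mid: math.log(lo) for mid, (lo, hi) in box.items() if lo == hi}
    free = [mid for mid in mids if mid not in fixed]
    lo = np.array([math.log(box[mid][0]) for mid in free])
    hi = np.array([math.log(box[mid][1]) for mid in free])

    def full_point(z: np.ndarray) -> dict[str, float]:
        x = dict(fixed)
        x.update({mid: float(zi) for mid, zi in zip(free, z)})
        return x

    def f(z: np.ndarray) -> float:
        # optimize ln(cost): same minimizer, tamer dynamic range for the
        # numeric-gradient quasi-Newton steps
        return math.log(ecm_objective(full_point(z), terms))

    if not free:
        x_full = dict(fixed)
        value = ecm_objective(x_full, terms)
        if value >= _PENALTY:
            raise ValueError(
                f"pathway {flux.name!r}: fixed concentrations are thermodynamically infeasible"
            )
        return _build_result(x_full, terms, flux, value, converged=True)

    x_mdf = mdf_concentrations(model, flux, box)
    starts = [np.array([x_mdf[mid] for mid in free])]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        w = rng.uniform(0.15, 0.85, size=len(free))
        starts.append(lo + w * (hi - lo))

    best_z, best_val = None, math.inf
    for z0 in starts:
        res = minimize(
            f,
            z0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 2000},
        )
        if res.fun < best_val:
            best_z, best_val = res.x, float(res.fun)
    if best_z is None or best_val >= math.log(_PENALTY):  # pragma: no cover
        raise RuntimeError(f"ECM failed to converge for {flux.name!r}")
    # polish once from the best point
    res = minimize(
        f, best_z, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 5000},
    )
    if res.fun < best_val:
        z = np.clip(res.x, lo, hi)
        val = f(z)
        if val < best_val:
            best_z, best_val = z, val
    objective = ecm_objective(full_point(best_z), terms)
    return _build_result(full_point(best_z), terms, flux, objective, converged=True)


def _most_constrained(
    model: NetworkModel, flux: FluxDistribution, box: ConcentrationBounds
) -> str:
    """Reaction with the smallest best-case driving force in the box."""
    worst_rid, worst_theta = "", math.inf
    for rid, v in flux.fluxes.items():
        if v <= 0:
            continue
        r = model.reaction(rid)
        theta = math.log(r.keq)
        for mid, coeff in r.stoichiometry.items():
            lo, hi = box[mid]
            # best case: substrates at upper bound, products at lower bound
            theta -= float(coeff) * (math.log(lo) if coeff > 0 else math.log(hi))
        if theta < worst_theta:
            worst_rid, worst_theta = rid, theta
    return f"{worst_rid} (best-case driving force {worst_theta:.3g})"


def _build_result(
    x_full: dict[str, float],
    terms: list[tuple[Reaction, float, BalancedKinetics]],
    flux: FluxDistribution,
    objective: float,
    converged: bool,
) -> ECMResult:
    breakdowns = tuple(
        enzyme_demand(reaction, v, bk, x_full) for reaction, v, bk in terms
    )
    total = sum(
        r.enzyme_mass * bd.demand for (r, _, _), bd in zip(terms, breakdowns)
    )
    return ECMResult(
        log_conc=dict(x_full),
        breakdowns=breakdowns,
        total_enzyme_mass=total,
        specific_activity=60.0 * flux.product_rate / total,
        converged=converged,
        objective_value=objective,
    )


def specific_activity(result: ECMResult) -> float:
    """Pathway-specific activity, umol/min per mg total enzyme."""
    if not result.converged:
        raise ValueError("specific_activity requires a converged ECM result")
    return result.specific_activity


def monte_carlo_activity(
    model: NetworkModel,
    flux: FluxDistribution,
    kinetics: dict[str, BalancedKinetics],
    bounds: ConcentrationBounds | None = None,
    n: int = 100,
    seed: int = 0,
    priors: PriorSpec | None = None,
) -> tuple[float, float]:
    """Geometric mean and geometric SD of the specific activity under
    lognormal parameter uncertainty.

    Each iteration multiplies every kinetic parameter by a lognormal
    deviate with its posterior gsd, re-imposes the Haldane relationship by
    re-balancing the perturbed values as data (Keq stays fixed), and
    re-runs ECM.  Infeasible iterations are dropped; more than 50% drops
    raise an error.
    """
    if n < 2:
        raise ValueError("monte_carlo_activity needs n >= 2")
    rng = np.random.default_rng(seed)
    activities: list[float] = []
    dropped = 0
    for _ in range(n):
        perturbed: dict[str, BalancedKinetics] = {}
        for rid, bk in kinetics.items():
            if flux.fluxes.get(rid, 0.0) <= 0:
                continue
            reaction = model.reaction(rid)
            records = []
            for name, value in _iter_params(bk):
                gsd = max(bk.posterior_gsd.get(name, 1.0), 1.0)
                noisy = value * math.exp(math.log(gsd) * rng.standard_normal())
                qty, _, compound = name.partition(":")
                records.append(
                    ParameterRecord(
                        reaction_id=rid,
                        quantity="km" if qty == "km" else qty,
                        value=noisy,
                        gsd=max(gsd, 1.001),
                        compound=compound,
                    )
                )
            perturbed[rid] = balance_reaction(reaction, records, priors)
        try:
            result = minimize_enzyme_cost(model, flux, perturbed, bounds, seed=seed)
            activities.append(result.specific_activity)
        except (ValueError, RuntimeError):
            dropped += 1
    if dropped > n / 2:
        raise RuntimeError(
            f"monte_carlo_activity: {dropped}/{n} iterations infeasible"
        )
    logs = np.log(activities)
    gmean = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if len(logs) > 1 else 1.0
    return gmean, gsd


def _iter_params(bk: BalancedKinetics):
    yield "kcat_forward", bk.kcat_forward
    yield "kcat_backward", bk.kcat_backward
    for mid, km in bk.km.items():
        yield f"km:{mid}", km
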