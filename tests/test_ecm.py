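"""Enzyme cost minimization: cost factors, optimizer, Monte-Carlo uncertainty."""

import math

import numpy as np
import pytest

from pathcost import (
    BalancedKinetics,
    FluxDistribution,
    Metabolite,
    NetworkModel,
    Reaction,
    enzyme_demand,
    generate_true_kinetics,
    minimize_enzyme_cost,
    monte_carlo_activity,
    random_toy_network,
    reversibility_factor,
    saturation_factor,
    SyntheticSpec,
)
from pathcost.ecm import ECMResult, ecm_objective, specific_activity, _cost_terms
from pathcost.synthetic import brute_force_ecm


class TestReversibilityFactor:
    def test_ln2_gives_half(self):
        assert reversibility_factor(math.log(2)) == pytest.approx(0.5)

    def test_large_driving_force_saturates_at_one(self):
        assert reversibility_factor(20.0) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [0.0, -1.0])
    def test_nonpositive_driving_force_is_an_error(self, theta):
        with pytest.raises(ValueError, match="infeasible"):
            reversibility_factor(theta)


class TestSaturationFactor:
    def test_single_substrate_at_km(self):
        r = Reaction(id="r", stoichiometry={"S": -1, "P": 1}, keq=10.0)
        km = {"S": 1e-4, "P": 1e-4}
        val = saturation_factor(r, {"S": 1e-4, "P": 1e-12}, km)
        assert val == pytest.approx(0.5, rel=1e-6)

    def test_saturated_substrate_no_product(self):
        r = Reaction(id="r", stoichiometry={"S": -1, "P": 1}, keq=10.0)
        km = {"S": 1e-6, "P": 1e-4}
        val = saturation_factor(r, {"S": 1e-2, "P": 1e-12}, km)
        assert val == pytest.approx(1.0, rel=1e-3)

    def test_bimolecular_all_at_km(self):
        # A + B -> C, everything at its Km: 1/((1+1)^2 + (1+1) - 1) = 0.2
        r = Reaction(id="r", stoichiometry={"A": -1, "B": -1, "C": 1}, keq=10.0)
        km = {"A": 1e-4, "B": 1e-4, "C": 1e-4}
        conc = {"A": 1e-4, "B": 1e-4, "C": 1e-4}
        assert saturation_factor(r, conc, km) == pytest.approx(0.2, rel=1e-9)

    def test_monotone_in_substrate_and_product(self):
        r = Reaction(id="r", stoichiometry={"S": -1, "P": 1}, keq=10.0)
        km = {"S": 1e-4, "P": 1e-4}
        svals = [saturation_factor(r, {"S": c, "P": 1e-5}, km) for c in np.logspace(-6, -2, 9)]
        assert all(a < b for a, b in zip(svals, svals[1:]))
        pvals = [saturation_factor(r, {"S": 1e-4, "P": c}, km) for c in np.logspace(-6, -2, 9)]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_missing_km_is_an_error(self):
        r = Reaction(id="r", stoichiometry={"S": -1, "P": 1}, keq=10.0)
        with pytest.raises(ValueError, match="missing Km"):
            saturation_factor(r, {"S": 1e-4, "P": 1e-4}, {"S": 1e-4})


class TestEnzymeDemand:
    def _setup(self):
        r = Reaction(id="r", stoichiometry={"A": -1, "B": 1}, keq=1e4, enzyme_mass=100.0)
        bk = BalancedKinetics(
            reaction_id="r", kcat_forward=10.0, kcat_backward=1e-3,
            km={"A": 1e-4, "B": 1e-4}, keq=1e4,
        )
        return r, bk

    def test_breakdown_identity(self):
        r, bk = self._setup()
        x = {"A": math.log(1e-3), "B": math.log(1e-5)}
        bd = enzyme_demand(r, 1.0, bk, x)
        # demand * eta_rev * eta_sat * kcat+ = v
        assert bd.demand * bd.reversibility_factor * bd.saturation_factor * 10.0 == (
            pytest.approx(1.0, rel=1e-12)
        )
        assert bd.demand >= bd.capacity_term

    def test_capacity_only_limit(self):
        r, bk = self._setup()
        # very saturated substrate, trace product: eta factors near 1
        x = {"A": math.log(1e-1), "B": math.log(1e-9)}
        bd = enzyme_demand(r, 1.0, bk, x)
        assert bd.demand == pytest.approx(bd.capacity_term, rel=0.05)

    def test_demand_nonincreasing_in_substrate(self):
        r, bk = self._setup()
        demands = [
            enzyme_demand(r, 1.0, bk, {"A": math.log(c), "B": math.log(1e-6)}).demand
            for c in np.logspace(-5, -2, 8)
        ]
        assert all(a >= b for a, b in zip(demands, demands[1:]))


def _fixed_model(keq=1e4):
    model = NetworkModel(
        metabolites=(
            Metabolite(id="A", role="exchanged", default_bounds=(1e-2, 1e-2)),
            Metabolite(id="B", role="exchanged", default_bounds=(1e-6, 1e-6)),
        ),
        reactions=(
            Reaction(id="r", stoichiometry={"A": -1, "B": 1}, keq=keq, enzyme_mass=100.0),
        ),
    )
    flux = FluxDistribution(name="f", fluxes={"r": 1.0}, product="B")
    kin = {
        "r": BalancedKinetics(
            reaction_id="r", kcat_forward=10.0, kcat_backward=10.0 * 1e-4 / (keq * 1e-4),
            km={"A": 1e-4, "B": 1e-4}, keq=keq,
        )
    }
    return model, flux, kin


class TestMinimizeEnzymeCost:
    def test_zero_dimensional_closed_form(self):
        model, flux, kin = _fixed_model()
        result = minimize_enzyme_cost(model, flux, kin)
        x = {"A": math.log(1e-2), "B": math.log(1e-6)}
        expected = ecm_objective(x, _cost_terms(model, flux, kin))
        assert result.objective_value == pytest.approx(expected, rel=1e-12)
        assert result.converged

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_chains(self, seed):
        model, flux = random_toy_network(0, 3, seed=seed)
        kin = {
            bk.reaction_id: bk
            for bk in generate_true_kinetics(model, SyntheticSpec(seed=seed))
        }
        result = minimize_enzyme_cost(model, flux, kin, seed=0)
        oracle = brute_force_ecm(model, flux, kin, grid_points=30)
        assert result.objective_value <= oracle * 1.01

    def test_widening_bounds_never_costs_more(self):
        model, flux = random_toy_network(0, 3, seed=1)
        kin = {
            bk.reaction_id: bk
            for bk in generate_true_kinetics(model, SyntheticSpec(seed=1))
        }
        base = {m.id: m.default_bounds for m in model.metabolites}
        cost0 = minimize_enzyme_cost(model, flux, kin, base, seed=0).objective_value
        for mid in ["M1", "M2"]:
            wider = dict(base)
            lo, hi = wider[mid]
            wider[mid] = (lo / 10, hi * 10)
            cost = minimize_enzyme_cost(model, flux, kin, wider, seed=0).objective_value
            assert cost <= cost0 * (1 + 1e-6)

    def test_objective_is_convex_along_segments(self):
        model, flux = random_toy_network(0, 3, seed=2)
        kin = {
            bk.reaction_id: bk
            for bk in generate_true_kinetics(model, SyntheticSpec(seed=2))
        }
        terms = _cost_terms(model, flux, kin)
        rng = np.random.default_rng(0)
        free = ["M1", "M2"]
        fixed = {"M0": math.log(1e-2), "M3": math.log(1e-5)}
        checked = 0
        while checked < 200:
            za, zb = rng.uniform(math.log(1e-6), math.log(1e-2), size=(2, len(free)))
            xa = {**fixed, **dict(zip(free, za))}
            xb = {**fixed, **dict(zip(free, zb))}
            xm = {**fixed, **dict(zip(free, (za + zb) / 2))}
            fa, fb, fm = (ecm_objective(x, terms) for x in (xa, xb, xm))
            if fa >= 1e29 or fb >= 1e29:
                continue
            assert fm <= (fa + fb) / 2 + 1e-9 * (fa + fb)
            checked += 1

    def test_infeasible_box_raises_naming_reaction(self):
        model, flux, kin = _fixed_model(keq=1.0)
        bounds = {"A": (1e-6, 1e-6), "B": (1e-2, 1e-2)}  # uphill, fixed
        with pytest.raises(ValueError, match="infeasible"):
            minimize_enzyme_cost(model, flux, kin, bounds)


class TestSpecificActivity:
    def test_unit_conversion(self):
        result = ECMResult(
            log_conc={}, breakdowns=(), total_enzyme_mass=40.0,
            specific_activity=60.0 / 40.0, converged=True, objective_value=40.0,
        )
        assert specific_activity(result) == pytest.approx(1.5)

    def test_doubling_masses_halves_activity(self):
        model, flux, kin = _fixed_model()
        a1 = minimize_enzyme_cost(model, flux, kin).specific_activity
        heavy = NetworkModel(
            metabolites=model.metabolites,
            reactions=tuple(
                Reaction(
                    id=r.id, stoichiometry=dict(r.stoichiometry),
                    enzyme_mass=2 * r.enzyme_mass, z_protons=r.z_protons, keq=r.keq,
                )
                for r in model.reactions
            ),
        )
        a2 = minimize_enzyme_cost(heavy, flux, kin).specific_activity
        assert a2 == pytest.approx(a1 / 2, rel=1e-9)


class TestMonteCarlo:
    def test_degenerate_noise_reproduces_point_estimate(self):
        model, flux, kin = _fixed_model()
        point = minimize_enzyme_cost(model, flux, kin).specific_activity
        gmean, gsd = monte_carlo_activity(model, flux, kin, n=5, seed=0)
        assert gsd == pytest.approx(1.0, abs=1e-6)
        assert gmean == pytest.approx(point, rel=1e-3)

    def test_fixed_seed_reproducible(self):
        model, flux = random_toy_network(0, 2, seed=3)
        spec = SyntheticSpec(seed=3)
        kin = {}
        for reaction, bk in zip(model.reactions, generate_true_kinetics(model, spec)):
            # give parameters genuine posterior spreads
            bk.posterior_gsd.update({f"km:{m}": 1.2 for m in reaction.stoichiometry})
            bk.posterior_gsd.update({"kcat_forward": 1.3, "kcat_backward": 1.3})
            kin[reaction.id] = bk
        r1 = monte_carlo_activity(model, flux, kin, n=6, seed=42)
        r2 = monte_carlo_activity(model, flux, kin, n=6, seed=42)
        r3 = monte_carlo_activity(model, flux, kin, n=6, seed=43)
        assert r1 == r2
        assert r1 != r3
        assert r1[1] > 1.0

    def test_needs_at_least_two_iterations(self):
        model, flux, kin = _fixed_model()
        with pytest.raises(ValueError):
            monte_carlo_activity(model, flux, kin, n=1)
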