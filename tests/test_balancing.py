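"""Parameter balancing: KKT minimizer, Haldane residuals, uncertainty inflation."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import minimize

from pathcost import (
    BalancedKinetics,
    ParameterRecord,
    PriorSpec,
    Reaction,
    balance_reaction,
    check_haldane,
    inflate_until_consistent,
)
from pathcost.balancing import HALDANE_TOL, assemble_problem


def _scipy_oracle(problem):
    """Independent minimizer of the same constrained objective (SLSQP)."""

    def objective(q):
        return float(np.sum(((problem.A @ q - problem.y) / problem.sigma) ** 2))

    res = minimize(
        objective,
        np.zeros(len(problem.names)),
        method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda q: problem.c @ q - problem.rhs}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    assert res.success
    return dict(zip(problem.names, np.exp(res.x)))


class TestAssembleProblem:
    def test_priors_only(self, ab_reaction, priors):
        p = assemble_problem(ab_reaction, [], priors)
        # priors on kcat+ and both Kms; kcat- is constraint-determined
        assert p.A.shape == (3, 4)
        assert p.rhs == pytest.approx(math.log(100))

    def test_one_record_adds_unit_row(self, ab_reaction, priors):
        rec = ParameterRecord("r1", "kcat_forward", 20.0, 1.5)
        p = assemble_problem(ab_reaction, [rec], priors)
        assert p.A.shape == (4, 4)
        np.testing.assert_allclose(p.A[-1], [1, 0, 0, 0])
        assert p.y[-1] == pytest.approx(math.log(20))

    def test_all_four_measured(self, ab_reaction, priors):
        recs = [
            ParameterRecord("r1", "kcat_forward", 10.0, 1.5),
            ParameterRecord("r1", "kcat_backward", 1.0, 1.5),
            ParameterRecord("r1", "km", 1e-4, 1.5, compound="A"),
            ParameterRecord("r1", "km", 1e-3, 1.5, compound="B"),
        ]
        p = assemble_problem(ab_reaction, recs, priors)
        assert p.A.shape == (3 + 4, 4)

    def test_record_for_other_reaction_rejected(self, ab_reaction, priors):
        rec = ParameterRecord("other", "kcat_forward", 1.0, 1.5)
        with pytest.raises(ValueError):
            assemble_problem(ab_reaction, [rec], priors)


class TestBalanceReaction:
    def test_no_data_discrepancy_goes_to_kcat_backward(self, ab_reaction, priors):
        # With priors on kcat+ and the Kms only, the Keq discrepancy is
        # absorbed entirely by the unpenalized kcat-: kcat+/kcat- = Keq.
        bk = balance_reaction(ab_reaction, [], priors)
        assert bk.kcat_forward == pytest.approx(10.0, rel=1e-9)
        assert bk.kcat_backward == pytest.approx(0.1, rel=1e-9)
        assert bk.km["A"] == pytest.approx(bk.km["B"], rel=1e-9)
        assert bk.km["A"] == pytest.approx(1e-4, rel=1e-9)
        assert abs(check_haldane(bk, ab_reaction)) < 1e-12

    def test_consistent_tight_data_returned_unchanged(self, ab_reaction):
        # kcat+/kcat- * KmB/KmA = 10/1 * 1e-3/1e-4 = 100 = Keq
        recs = [
            ParameterRecord("r1", "kcat_forward", 10.0, 1.001),
            ParameterRecord("r1", "kcat_backward", 1.0, 1.001),
            ParameterRecord("r1", "km", 1e-4, 1.001, compound="A"),
            ParameterRecord("r1", "km", 1e-3, 1.001, compound="B"),
        ]
        bk = balance_reaction(ab_reaction, recs)
        assert bk.kcat_forward == pytest.approx(10.0, rel=1e-5)
        assert bk.kcat_backward == pytest.approx(1.0, rel=1e-5)
        assert bk.km["A"] == pytest.approx(1e-4, rel=1e-5)
        assert bk.km["B"] == pytest.approx(1e-3, rel=1e-5)

    def test_conflicting_kcats_match_independent_minimizer(self, ab_reaction, priors):
        recs = [
            ParameterRecord("r1", "kcat_forward", 10.0, 1.5),
            ParameterRecord("r1", "kcat_backward", 10.0, 1.5),
            ParameterRecord("r1", "km", 1e-4, 1.5, compound="A"),
            ParameterRecord("r1", "km", 1e-4, 1.5, compound="B"),
        ]
        bk = balance_reaction(ab_reaction, recs, priors)
        oracle = _scipy_oracle(assemble_problem(ab_reaction, recs, priors))
        assert bk.kcat_forward == pytest.approx(oracle["kcat_forward"], rel=1e-5)
        assert bk.kcat_backward == pytest.approx(oracle["kcat_backward"], rel=1e-5)
        assert bk.km["A"] == pytest.approx(oracle["km:A"], rel=1e-5)
        assert bk.km["B"] == pytest.approx(oracle["km:B"], rel=1e-5)
        assert abs(check_haldane(bk, ab_reaction)) < HALDANE_TOL

    def test_keq_is_copied_bit_identical(self, ab_reaction, priors):
        bk = balance_reaction(ab_reaction, [], priors)
        assert bk.keq == ab_reaction.keq

    def test_posterior_never_wider_than_prior(self, ab_reaction, priors):
        recs = [
            ParameterRecord("r1", "kcat_forward", 25.0, 1.5),
            ParameterRecord("r1", "km", 2e-4, 2.0, compound="A"),
        ]
        bk = balance_reaction(ab_reaction, recs, priors)
        assert bk.posterior_gsd["kcat_forward"] <= priors.kcat_gsd + 1e-9
        assert bk.posterior_gsd["km:A"] <= priors.km_gsd + 1e-9
        assert bk.posterior_gsd["km:B"] <= priors.km_gsd + 1e-9
        assert math.isfinite(bk.posterior_gsd["kcat_backward"])

    def test_multi_substrate_haldane_exponents(self, priors):
        # 2 A + B <=> C: Haldane uses Km_A^2
        r = Reaction(
            id="r2",
            stoichiometry={"A": Fraction(-2), "B": Fraction(-1), "C": Fraction(1)},
            keq=1e3,
        )
        bk = balance_reaction(r, [], priors)
        assert abs(check_haldane(bk, r)) < 1e-10
        lhs = (
            bk.kcat_forward * bk.km["C"] / (bk.kcat_backward * bk.km["A"] ** 2 * bk.km["B"])
        )
        assert lhs == pytest.approx(1e3, rel=1e-6)


class TestCheckHaldane:
    def test_exact_set_has_zero_residual(self, ab_reaction):
        bk = BalancedKinetics(
            reaction_id="r1", kcat_forward=10.0, kcat_backward=1.0,
            km={"A": 1e-4, "B": 1e-3}, keq=100.0,
        )
        assert check_haldane(bk, ab_reaction) == pytest.approx(0.0, abs=1e-12)

    def test_e_fold_perturbation_gives_unit_residual(self, ab_reaction):
        bk = BalancedKinetics(
            reaction_id="r1", kcat_forward=10.0 * math.e, kcat_backward=1.0,
            km={"A": 1e-4, "B": 1e-3}, keq=100.0,
        )
        assert check_haldane(bk, ab_reaction) == pytest.approx(1.0, rel=1e-12)


class TestInflation:
    def test_consistent_data_takes_zero_rounds(self, ab_reaction, priors):
        recs = [ParameterRecord("r1", "kcat_forward", 12.0, 1.5)]
        result = inflate_until_consistent(ab_reaction, recs, priors)
        assert result.rounds == 0
        assert abs(check_haldane(result.kinetics, ab_reaction)) < HALDANE_TOL

    def test_gross_conflict_inflates_then_reconciles(self, ab_reaction, priors):
        # kcat+ = kcat- with equal tight Kms contradicts Keq = 100 by ln(100)
        recs = [
            ParameterRecord("r1", "kcat_forward", 10.0, 1.05),
            ParameterRecord("r1", "kcat_backward", 10.0, 1.05),
            ParameterRecord("r1", "km", 1e-4, 1.05, compound="A"),
            ParameterRecord("r1", "km", 1e-4, 1.05, compound="B"),
        ]
        result = inflate_until_consistent(ab_reaction, recs, priors, 1.5, 10)
        assert result.rounds >= 1
        assert abs(check_haldane(result.kinetics, ab_reaction)) < HALDANE_TOL

    def test_max_iter_exceeded_raises(self, ab_reaction, priors):
        recs = [
            ParameterRecord("r1", "kcat_forward", 10.0, 1.01),
            ParameterRecord("r1", "kcat_backward", 10.0, 1.01),
            ParameterRecord("r1", "km", 1e-4, 1.01, compound="A"),
            ParameterRecord("r1", "km", 1e-4, 1.01, compound="B"),
        ]
        with pytest.raises(RuntimeError, match="inconsistent"):
            inflate_until_consistent(ab_reaction, recs, priors, 1.5, 0)

    def test_inflate_factor_must_widen(self, ab_reaction, priors):
        with pytest.raises(ValueError):
            inflate_until_consistent(ab_reaction, [], priors, inflate_factor=1.0)
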