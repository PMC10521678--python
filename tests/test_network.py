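"""Network domain types, TSV dialect I/O, stoichiometry operations."""

from fractions import Fraction

import numpy as np
import pytest

from pathcost import (
    FluxDistribution,
    Metabolite,
    NetworkModel,
    Reaction,
    net_stoichiometry,
    read_model,
    stoichiometric_matrix,
    validate_flux,
    write_model,
)
from pathcost.sbtab_io import format_reaction_formula, parse_reaction_formula


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("A <=> B", {"A": -1, "B": 1}),
        ("2 A + B <=> C", {"A": -2, "B": -1, "C": 1}),
        ("1/2 A <=> 3/2 B", {"A": Fraction(-1, 2), "B": Fraction(3, 2)}),
        ("A + B <=> C + 2 D", {"A": -1, "B": -1, "C": 1, "D": 2}),
    ],
)
def test_reaction_formula_round_trip(formula, expected):
    stoich = parse_reaction_formula(formula)
    assert stoich == {m: Fraction(c) for m, c in expected.items()}
    assert parse_reaction_formula(format_reaction_formula(stoich)) == stoich


@pytest.mark.parametrize("bad", ["A -> B", "<=> B", "A <=>", "0 A <=> B"])
def test_reaction_formula_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_reaction_formula(bad)


def test_read_model_minimal(model_files):
    model, records = read_model(*model_files)
    assert model.metabolite_ids == ["A", "B"]
    assert len(model.reactions) == 1
    r = model.reactions[0]
    assert r.keq == 100 and r.enzyme_mass == 50
    assert r.stoichiometry == {"A": Fraction(-1), "B": Fraction(1)}
    # row order preserved; mM Km converted to molar
    assert [rec.quantity for rec in records] == ["kcat_forward", "km", "keq"]
    assert records[1].value == pytest.approx(1e-4)


def test_read_write_round_trip(tmp_path, model_files):
    model, records = read_model(*model_files)
    mpath, dpath = tmp_path / "m2.tsv", tmp_path / "d2.tsv"
    write_model(model, mpath, records, dpath)
    model2, records2 = read_model(mpath, dpath)
    assert model2.metabolite_ids == model.metabolite_ids
    assert [r.id for r in model2.reactions] == [r.id for r in model.reactions]
    for r1, r2 in zip(model.reactions, model2.reactions):
        assert r1.stoichiometry == r2.stoichiometry
        assert r1.keq == pytest.approx(r2.keq, rel=1e-12)
    for a, b in zip(records, records2):
        assert (a.reaction_id, a.quantity, a.compound) == (b.reaction_id, b.quantity, b.compound)
        assert a.value == pytest.approx(b.value, rel=1e-12)


@pytest.mark.parametrize(
    "mutation, match",
    [
        (("!Value", "10", "-1"), "value must be > 0"),
        (("!GSD", "1.5", "0.9"), "GSD must be >= 1"),
        (("km\tA", "km\tZ"), "does not participate"),
    ],
)
def test_read_model_bad_rows(tmp_path, model_files, mutation, match):
    mpath, dpath = model_files
    text = dpath.read_text()
    if len(mutation) == 3:
        col, old, new = mutation
        # only mutate the kcat row's value/gsd field
        lines = text.splitlines()
        lines[2] = lines[2].replace(old, new)
        text = "\n".join(lines)
    else:
        text = text.replace(*mutation)
    bad = tmp_path / "bad.tsv"
    bad.write_text(text)
    with pytest.raises(ValueError, match=match):
        read_model(mpath, bad)


def test_duplicate_ids_rejected(tmp_path, model_files):
    mpath, _ = model_files
    text = mpath.read_text()
    dup = tmp_path / "dup.tsv"
    dup.write_text(text + "r1\tA <=> B\t100\t1.2\t50\t0\n")
    with pytest.raises(ValueError, match="r1"):
        read_model(dup)


def test_unknown_columns_warned_not_fatal(tmp_path, caplog):
    text = (
        "!!SBtab TableType='Reaction'\n"
        "!ID\t!ReactionFormula\t!Keq\t!Bogus\n"
        "r1\tA <=> B\t10\tx\n"
    )
    p = tmp_path / "m.tsv"
    p.write_text(text)
    import logging

    with caplog.at_level(logging.WARNING):
        model, _ = read_model(p)
    assert len(model.reactions) == 1
    assert any("!Bogus" in rec.message for rec in caplog.records)


def test_stoichiometric_matrix_columns():
    m = NetworkModel(
        metabolites=(Metabolite(id="A"), Metabolite(id="B")),
        reactions=(
            Reaction(id="r1", stoichiometry={"A": -1, "B": 1}, keq=1.0),
            Reaction(id="r2", stoichiometry={"A": -2, "B": 1}, keq=1.0),
        ),
    )
    N = stoichiometric_matrix(m)
    assert N.shape == (2, 2)
    np.testing.assert_allclose(N[:, 0], [-1, 1])
    np.testing.assert_allclose(N[:, 1], [-2, 1])
    empty = NetworkModel(metabolites=(), reactions=())
    assert stoichiometric_matrix(empty).shape == (0, 0)


@pytest.fixture
def chain_model():
    return NetworkModel(
        metabolites=(
            Metabolite(id="A", role="exchanged"),
            Metabolite(id="B", role="internal"),
            Metabolite(id="C", role="exchanged"),
        ),
        reactions=(
            Reaction(id="r1", stoichiometry={"A": -1, "B": 1}, keq=10.0),
            Reaction(id="r2", stoichiometry={"B": -1, "C": 1}, keq=10.0),
        ),
    )


def test_net_stoichiometry_cancels_internal(chain_model):
    flux = FluxDistribution(name="f", fluxes={"r1": 1, "r2": 1}, product="C")
    assert net_stoichiometry(chain_model, flux) == {"A": -1.0, "C": 1.0}


def test_net_stoichiometry_is_linear_in_flux(chain_model):
    f1 = FluxDistribution(name="f1", fluxes={"r1": 1, "r2": 1}, product="C")
    f2 = FluxDistribution(name="f2", fluxes={"r1": 2, "r2": 2}, product="C")
    f3 = FluxDistribution(name="f3", fluxes={"r1": 3, "r2": 3}, product="C")
    n1, n2, n3 = (net_stoichiometry(chain_model, f) for f in (f1, f2, f3))
    for mid in n3:
        assert n3[mid] == pytest.approx(n1[mid] + n2[mid])


def test_net_stoichiometry_rejects_unbalanced_internal(chain_model):
    flux = FluxDistribution(name="f", fluxes={"r1": 1, "r2": 0.9}, product="C")
    with pytest.raises(ValueError, match="'B'"):
        net_stoichiometry(chain_model, flux)


def test_validate_flux_reports(chain_model):
    good = FluxDistribution(name="ok", fluxes={"r1": 1, "r2": 1}, product="C")
    assert validate_flux(chain_model, good).passed
    bad = FluxDistribution(name="bad", fluxes={"r1": 1, "r2": 0.9}, product="C")
    report = validate_flux(chain_model, bad)
    assert not report.passed and "B" in report.imbalances
    empty = FluxDistribution(name="empty", fluxes={}, product="C")
    assert validate_flux(chain_model, empty).passed


def test_invariants_of_domain_types():
    with pytest.raises(ValueError):
        Reaction(id="r", stoichiometry={"A": -1}, keq=1.0)  # no product
    with pytest.raises(ValueError):
        Reaction(id="r", stoichiometry={"A": -1, "B": 1}, keq=-1.0)
    with pytest.raises(ValueError):
        Metabolite(id="A", default_bounds=(0.0, 1e-3))
    with pytest.raises(ValueError, match="duplicate"):
        NetworkModel(
            metabolites=(Metabolite(id="A"), Metabolite(id="A")), reactions=()
        )
    with pytest.raises(ValueError, match="unknown metabolite"):
        NetworkModel(
            metabolites=(Metabolite(id="A"),),
            reactions=(Reaction(id="r", stoichiometry={"A": -1, "B": 1}, keq=1.0),),
        )
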