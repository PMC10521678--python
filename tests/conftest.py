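from fractions import Fraction

import pytest

from pathcost import Metabolite, NetworkModel, PriorSpec, Reaction


@pytest.fixture
def ab_reaction() -> Reaction:
    """A <=> B with Keq = 100."""
    return Reaction(
        id="r1",
        stoichiometry={"A": Fraction(-1), "B": Fraction(1)},
        enzyme_mass=100.0,
        keq=100.0,
    )


@pytest.fixture
def ab_model(ab_reaction) -> NetworkModel:
    return NetworkModel(
        metabolites=(
            Metabolite(id="A", role="exchanged"),
            Metabolite(id="B", role="exchanged"),
        ),
        reactions=(ab_reaction,),
    )


@pytest.fixture
def priors() -> PriorSpec:
    return PriorSpec()


MODEL_TSV = """!!SBtab TableType='Compound'
!ID\t!Name\t!Role\t!LowerBoundM\t!UpperBoundM
A\tsubstrate\texchanged\t1e-6\t1e-2
B\tproduct\texchanged\t1e-6\t1e-2
!!SBtab TableType='Reaction'
!ID\t!ReactionFormula\t!Keq\t!KeqGSD\t!EnzymeMassKDa\t!TransportedProtons
r1\tA <=> B\t100\t1.2\t50\t0
"""

DATA_TSV = """!!SBtab TableType='Quantity'
!ReactionID\t!QuantityType\t!Compound\t!Value\t!Unit\t!GSD
r1\tkcat_forward\t\t10\t1/s\t1.5
r1\tkm\tA\t0.1\tmM\t2
r1\tkeq\t\t100\tdimensionless\t1.2
"""


@pytest.fixture
def model_files(tmp_path):
    model_path = tmp_path / "model.tsv"
    data_path = tmp_path / "data.tsv"
    model_path.write_text(MODEL_TSV)
    data_path.write_text(DATA_TSV)
    return model_path, data_path
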