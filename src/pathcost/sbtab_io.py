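"""Readers/writers for the SBtab-dialect tab-separated model and data files.

The dialect is deliberately frozen to a fixed column set:

Model file
    table ``Reaction``: ``!ID  !ReactionFormula  !Keq  !KeqGSD  !EnzymeMassKDa
    !TransportedProtons``; table ``Compound``: ``!ID  !Name  !Role
    !LowerBoundM  !UpperBoundM`` (optional ``!CarbonCount  !ElectronCount``).

Data file
    table ``Quantity``: ``!ReactionID  !QuantityType  !Compound  !Value
    !Unit  !GSD`` with quantity types ``kcat_forward | kcat_backward | km |
    keq`` and units ``1/s | M | mM | uM | dimensionless``.

Reaction formulas follow the grammar ``"2 A + 1/2 B <=> C"``: rational or
decimal coefficients, ``" + "`` separators, ``" <=> "`` arrow.  Tables are
introduced by a ``!!SBtab ... TableType='...'`` line followed by the header
row.  Unknown columns are ignored with a logged warning; concentrations are
converted to molar on read.
"""

from __future__ import annotations

import logging
import re
from fractions import Fraction
from pathlib import Path

from .network import (
    FluxDistribution,
    Metabolite,
    NetworkModel,
    ParameterRecord,
    Reaction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_model",
    "write_model",
    "read_tables",
    "parse_reaction_formula",
    "format_reaction_formula",
    "write_pathway_fixture",
    "read_pathway_tables",
]

_ARROW = "<=>"

_CONC_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6}

_REACTION_COLUMNS = {
    "!ID", "!ReactionFormula", "!Keq", "!KeqGSD", "!EnzymeMassKDa", "!TransportedProtons",
}
_COMPOUND_COLUMNS = {
    "!ID", "!Name", "!Role", "!LowerBoundM", "!UpperBoundM", "!CarbonCount", "!ElectronCount",
}
_QUANTITY_COLUMNS = {"!ReactionID", "!QuantityType", "!Compound", "!Value", "!Unit", "!GSD"}


def parse_reaction_formula(formula: str) -> dict[str, Fraction]:
    """Parse ``"2 A + B <=> C"`` into a signed stoichiometry map."""
    if _ARROW not in formula:
        raise ValueError(f"reaction formula must contain {_ARROW!r}: {formula!r}")
    lhs, rhs = formula.split(_ARROW, 1)
    stoich: dict[str, Fraction] = {}

    def _side(text: str, sign: int) -> None:
        text = text.strip()
        if not text:
            raise ValueError(f"empty reaction side in {formula!r}")
        for term in re.split(r"\s\+\s", text):
            parts = term.strip().split()
            if len(parts) == 1:
                coeff, mid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, mid = Fraction(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {formula!r}")
            if coeff <= 0:
                raise ValueError(f"non-positive coefficient in {formula!r}")
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coeff
    _side(lhs, -1)
    _side(rhs, +1)
    return {m: c for m, c in stoich.items() if c != 0}


def _fmt_coeff(c: Fraction) -> str:
    return "" if c == 1 else f"{c} "


def format_reaction_formula(stoich: dict[str, Fraction]) -> str:
    subs = " + ".join(f"{_fmt_coeff(-c)}{m}" for m, c in stoich.items() if c < 0)
    prods = " + ".join(f"{_fmt_coeff(c)}{m}" for m, c in stoich.items() if c > 0)
    return f"{subs} {_ARROW} {prods}"


def read_tables(path: str | Path) -> dict[str, list[dict[str, str]]]:
    """Parse a multi-table TSV file into ``{table_type: [row dicts]}``.

    Row dicts additionally carry ``"__line__"`` with the 1-based line number
    for error reporting.
    """
    tables: dict[str, list[dict[str, str]]] = {}
    current: list[dict[str, str]] | None = None
    header: list[str] | None = None
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("%"):
            continue
        if line.startswith("!!"):
            m = re.search(r"TableType='([^']+)'", line)
            if not m:
                raise ValueError(f"{path}:{lineno}: table declaration lacks TableType")
            ttype = m.group(1)
            current = tables.setdefault(ttype, [])
            header = None
            continue
        cells = line.split("\t")
        if current is None:
            raise ValueError(f"{path}:{lineno}: data before any table declaration")
        if header is None:
            header = [c.strip() for c in cells]
            continue
        row = {h: cells[i].strip() if i < len(cells) else "" for i, h in enumerate(header)}
        row["__line__"] = str(lineno)
        current.append(row)
    return tables


def _warn_unknown(rows: list[dict[str, str]], known: set[str], table: str, path) -> None:
    if rows:
        unknown = set(rows[0]) - known - {"__line__"}
        for col in sorted(unknown):
            logger.warning("%s: ignoring unknown column %s in table %s", path, col, table)


def _parse_compound(row: dict[str, str], path) -> Metabolite:
    line = row["__line__"]
    lb = float(row.get("!LowerBoundM") or 1e-6)
    ub = float(row.get("!UpperBoundM") or 1e-2)
    if lb <= 0 or ub <= 0 or lb > ub:
        raise ValueError(f"{path}:{line}: invalid bounds ({lb}, {ub})")
    return Metabolite(
        id=row["!ID"],
        name=row.get("!Name", ""),
        role=row.get("!Role") or "internal",
        default_bounds=(lb, ub),
        carbon_count=int(row.get("!CarbonCount") or 0),
        electron_count=float(row.get("!ElectronCount") or 0.0),
    )


def _parse_reaction(row: dict[str, str], path) -> Reaction:
    line = row["__line__"]
    keq = float(row.get("!Keq") or 1.0)
    keq_gsd = float(row.get("!KeqGSD") or 1.0)
    if keq <= 0:
        raise ValueError(f"{path}:{line}: Keq must be > 0, got {keq}")
    if keq_gsd < 1:
        raise ValueError(f"{path}:{line}: KeqGSD must be >= 1, got {keq_gsd}")
    mass = float(row.get("!EnzymeMassKDa") or 100.0)
    if mass <= 0:
        raise ValueError(f"{path}:{line}: EnzymeMassKDa must be > 0, got {mass}")
    return Reaction(
        id=row["!ID"],
        stoichiometry=parse_reaction_formula(row["!ReactionFormula"]),
        enzyme_mass=mass,
        z_protons=int(row.get("!TransportedProtons") or 0),
        keq=keq,
        keq_gsd=keq_gsd,
    )


def _parse_quantity(row: dict[str, str], model: NetworkModel, path) -> ParameterRecord:
    line = row["__line__"]
    qtype = row["!QuantityType"]
    try:
        value = float(row["!Value"])
    except ValueError as exc:
        raise ValueError(f"{path}:{line}: bad value {row['!Value']!r}") from exc
    if value <= 0:
        raise ValueError(f"{path}:{line}: value must be > 0, got {value}")
    gsd = float(row.get("!GSD") or 1.0)
    if gsd < 1:
        raise ValueError(f"{path}:{line}: GSD must be >= 1, got {gsd}")
    unit = row.get("!Unit", "")
    if qtype == "km":
        factor = _CONC_FACTORS.get(unit or "M")
        if factor is None:
            raise ValueError(f"{path}:{line}: unknown concentration unit {unit!r}")
        value *= factor
    rid = row["!ReactionID"]
    compound = row.get("!Compound", "")
    try:
        reaction = model.reaction(rid)
    except KeyError:
        raise ValueError(f"{path}:{line}: unknown reaction {rid!r}") from None
    if qtype == "km" and compound not in reaction.stoichiometry:
        raise ValueError(
            f"{path}:{line}: km compound {compound!r} does not participate in {rid}"
        )
    return ParameterRecord(reaction_id=rid, quantity=qtype, value=value, gsd=gsd, compound=compound)


def read_model(
    model_path: str | Path, data_path: str | Path | None = None
) -> tuple[NetworkModel, list[ParameterRecord]]:
    """Read a model TSV (and optional data TSV) into domain objects.

    Row order is preserved; unknown columns are ignored with a logged
    warning; malformed rows raise ``ValueError`` naming file and line.
    """
    tables = read_tables(model_path)
    compounds = tables.get("Compound", [])
    reactions = tables.get("Reaction", [])
    if not reactions:
        raise ValueError(f"{model_path}: no Reaction table found")
    _warn_unknown(compounds, _COMPOUND_COLUMNS, "Compound", model_path)
    _warn_unknown(reactions, _REACTION_COLUMNS, "Reaction", model_path)

    mets = [_parse_compound(row, model_path) for row in compounds]
    rxns = [_parse_reaction(row, model_path) for row in reactions]
    # metabolites referenced by formulas but not declared get default entries
    declared = {m.id for m in mets}
    for r in rxns:
        for mid in r.stoichiometry:
            if mid not in declared:
                mets.append(Metabolite(id=mid))
                declared.add(mid)
    model = NetworkModel(metabolites=tuple(mets), reactions=tuple(rxns))

    records: list[ParameterRecord] = []
    if data_path is not None:
        dtables = read_tables(data_path)
        quantities = dtables.get("Quantity", [])
        _warn_unknown(quantities, _QUANTITY_COLUMNS, "Quantity", data_path)
        records = [_parse_quantity(row, model, data_path) for row in quantities]
    return model, records


def write_model(
    model: NetworkModel,
    model_path: str | Path,
    records: list[ParameterRecord] | None = None,
    data_path: str | Path | None = None,
) -> None:
    """Write a model (and optionally records) back to the TSV dialect."""
    lines = ["!!SBtab TableType='Compound'"]
    lines.append(
        "!ID\t!Name\t!Role\t!LowerBoundM\t!UpperBoundM\t!CarbonCount\t!ElectronCount"
    )
    for m in model.metabolites:
        lb, ub = m.default_bounds
        lines.append(
            f"{m.id}\t{m.name}\t{m.role}\t{lb:.6g}\t{ub:.6g}\t{m.carbon_count}\t{m.electron_count:g}"
        )
    lines.append("!!SBtab TableType='Reaction'")
    lines.append("!ID\t!ReactionFormula\t!Keq\t!KeqGSD\t!EnzymeMassKDa\t!TransportedProtons")
    for r in model.reactions:
        lines.append(
            f"{r.id}\t{format_reaction_formula(dict(r.stoichiometry))}\t{r.keq:.12g}"
            f"\t{r.keq_gsd:.6g}\t{r.enzyme_mass:.6g}\t{r.z_protons}"
        )
    Path(model_path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    if records is not None:
        if data_path is None:
            raise ValueError("data_path required when writing records")
        dlines = ["!!SBtab TableType='Quantity'"]
        dlines.append("!ReactionID\t!QuantityType\t!Compound\t!Value\t!Unit\t!GSD")
        for rec in records:
            unit = {"km": "M", "keq": "dimensionless"}.get(rec.quantity, "1/s")
            dlines.append(
                f"{rec.reaction_id}\t{rec.quantity}\t{rec.compound}\t{rec.value:.12g}\t{unit}\t{rec.gsd:.6g}"
            )
        Path(data_path).write_text("\n".join(dlines) + "\n", encoding="utf-8")


def write_balanced(kinetics: list, path: str | Path) -> None:
    """Write balanced kinetic sets as a Quantity-style TSV with posterior GSDs."""
    lines = ["!!SBtab TableType='Quantity'"]
    lines.append("!ReactionID\t!QuantityType\t!Compound\t!Value\t!Unit\t!PosteriorGSD")

    def _row(bk, qtype: str, compound: str, value: float, unit: str) -> str:
        key = qtype if qtype != "km" else f"km:{compound}"
        gsd = bk.posterior_gsd.get(key, 1.0)
        return f"{bk.reaction_id}\t{qtype}\t{compound}\t{value:.12g}\t{unit}\t{gsd:.6g}"

    for bk in kinetics:
        lines.append(_row(bk, "kcat_forward", "", bk.kcat_forward, "1/s"))
        lines.append(_row(bk, "kcat_backward", "", bk.kcat_backward, "1/s"))
        for mid, km in bk.km.items():
            lines.append(_row(bk, "km", mid, km, "M"))
        lines.append(_row(bk, "keq", "", bk.keq, "dimensionless"))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_balanced(path: str | Path, model: NetworkModel) -> dict:
    """Read a balanced-kinetics TSV back into ``{reaction_id: BalancedKinetics}``."""
    from .balancing import BalancedKinetics

    tables = read_tables(path)
    rows = tables.get("Quantity", [])
    grouped: dict[str, dict] = {}
    for row in rows:
        rid = row["!ReactionID"]
        entry = grouped.setdefault(
            rid, {"km": {}, "posterior_gsd": {}, "keq": None, "kf": None, "kb": None}
        )
        qtype = row["!QuantityType"]
        value = float(row["!Value"])
        gsd = float(row.get("!PosteriorGSD") or 1.0)
        if qtype == "kcat_forward":
            entry["kf"] = value
            entry["posterior_gsd"]["kcat_forward"] = gsd
        elif qtype == "kcat_backward":
            entry["kb"] = value
            entry["posterior_gsd"]["kcat_backward"] = gsd
        elif qtype == "km":
            compound = row["!Compound"]
            entry["km"][compound] = value
            entry["posterior_gsd"][f"km:{compound}"] = gsd
        elif qtype == "keq":
            entry["keq"] = value
    out = {}
    for rid, entry in grouped.items():
        keq = entry["keq"] if entry["keq"] is not None else model.reaction(rid).keq
        out[rid] = BalancedKinetics(
            reaction_id=rid,
            kcat_forward=entry["kf"],
            kcat_backward=entry["kb"],
            km=entry["km"],
            keq=keq,
            posterior_gsd=entry["posterior_gsd"],
        )
    return out


def write_pathway_fixture(
    model: NetworkModel,
    flux: FluxDistribution,
    path: str | Path,
    comment: str = "",
) -> None:
    """Write a pathway fixture: model tables plus ``Pathway``/``Flux`` tables."""
    write_model(model, path)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if comment:
        lines.insert(0, f"% {comment}")
    lines.append("!!SBtab TableType='Pathway'")
    lines.append("!Name\t!Product\t!ProductRate")
    lines.append(f"{flux.name}\t{flux.product}\t{flux.product_rate:g}")
    lines.append("!!SBtab TableType='Flux'")
    lines.append("!ReactionID\t!Value")
    for rid, v in flux.fluxes.items():
        lines.append(f"{rid}\t{v:g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pathway_tables(path: str | Path) -> tuple[NetworkModel, FluxDistribution]:
    """Read a packaged pathway fixture: model tables plus ``Pathway``/``Flux``.

    The ``Pathway`` table (one row: ``!Name  !Product  !ProductRate``) names
    the entry; the ``Flux`` table (``!ReactionID  !Value``) carries the flux
    distribution.
    """
    model, _ = read_model(path)
    tables = read_tables(path)
    prow = tables.get("Pathway", [{}])[0]
    fluxes = {
        row["!ReactionID"]: float(row["!Value"]) for row in tables.get("Flux", [])
    }
    flux = FluxDistribution(
        name=prow.get("!Name", Path(path).stem),
        fluxes=fluxes,
        product=prow["!Product"],
        product_rate=float(prow.get("!ProductRate") or 1.0),
    )
    return model, flux
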