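"""Machine-readable registry of carbon-fixation pathways and connecting modules.

Entries are shipped as TSV fixtures in the model-file dialect (one per
pathway) and cover the natural and designed CO2/C1-fixation routes compared
in this package — the Calvin-Benson-Bassham (CBB) cycle and its
phosphatase-less variant, C4-type CO2-concentration shuttles, the reductive
citramalyl-CoA cycle (rCCC), the 2-hydroxyglutarate reverse TCA cycle, the
crenarchaeal and thaumarchaeal 3-HP/4-HB cycles, malyl-CoA/glycerate-type
cycles, and the product-converting connecting modules (glyoxylate ->
oxaloacetate, acetyl-CoA -> pyruvate, and friends).

Stoichiometries, flux distributions and proton-translocation counts follow
the published pathway definitions at the granularity of the pathway maps
(lumped steps expanded only where a printed ATP/yield number requires it).
Per-reaction equilibrium constants and enzyme masses in the fixtures are
synthetic placeholders: sufficient for stoichiometric analyses (ATP
ledgers, yields, balance checks), not a substitute for curated kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from ..network import (
    FluxDistribution,
    Metabolite,
    NetworkModel,
    net_stoichiometry,
    validate_flux,
)
from ..sbtab_io import read_pathway_tables

__all__ = ["PathwayEntry", "get_pathway", "list_pathways", "compose"]

_PROVENANCE = {
    "CBB": "Calvin-Benson-Bassham cycle, C3 form, per glyceraldehyde-3-phosphate",
    "CBB_PTS": "phosphatase-less CBB variant: phosphatases replaced by "
               "pyrophosphate-mediated phosphotransferases",
    "C4_shuttle_PEPS": "C4 malic-enzyme CO2 shuttle via PEP synthase (AMP-forming)",
    "C4_shuttle_PyrC": "C4-type CO2 shuttle via pyruvate carboxylase",
    "C4_CBB_PEPS": "CBB cycle fed by the PEP-synthase C4 shuttle (3 CO2 deliveries)",
    "C4_CBB_PyrC": "CBB cycle fed by the pyruvate-carboxylase C4 shuttle",
    "rCCC": "reductive citramalyl-CoA cycle: rTCA + CETCH + 3-HP-bicycle segments "
            "closed by pyruvate carboxylase",
    "HG_rTCA": "2-hydroxyglutarate reverse TCA cycle: rTCA with the "
               "2-oxoglutarate synthase step replaced by a 2-hydroxyacyl-CoA "
               "lyase extension with formyl-CoA",
    "HP4HB_thaum": "3-hydroxypropionate/4-hydroxybutyrate cycle, thaumarchaeal "
                   "(ADP-forming CoA ligases)",
    "HP4HB_cren": "3-hydroxypropionate/4-hydroxybutyrate cycle, crenarchaeal "
                  "(AMP-forming CoA ligases)",
    "MCG_like": "malyl-CoA/glycerate-type cycle using the beta-hydroxyaspartate "
                "cycle for glyoxylate assimilation and pyruvate carboxylase entry",
    "MCG_glycerate": "original malyl-CoA-glycerate cycle: glyoxylate carboligase/"
                     "glycerate route and PEP-synthase entry",
    "bOHAsp_module": "beta-hydroxyaspartate cycle: 2 glyoxylate -> oxaloacetate",
    "rCC_AcCoA_to_Pyr": "acetyl-CoA -> pyruvate module from rCCC plus three "
                        "ethylmalonyl-CoA-pathway reactions",
    "EMC_module": "ethylmalonyl-CoA pathway (modified): 2 acetyl-CoA -> 1.5 OAA",
    "HP4HB_AcCoA_to_OAA": "acetyl-CoA -> oxaloacetate module from the 3-HP/4-HB cycle",
    "RevGlyoxShunt": "reverse glyoxylate shunt: glyoxylate -> acetyl-CoA",
    "Serine_glyox_to_OAA": "serine-cycle module: glyoxylate + formate -> oxaloacetate",
    "GCL_GDH_module": "glyoxylate carboligase / glycerate dehydrogenase: "
                      "2 glyoxylate -> glycerate + CO2",
    "HPB_glyox_to_OAA": "3-HP-bicycle module (modified): glyoxylate -> oxaloacetate",
    "FourHB_Pyr_to_2AcCoA": "4-HB route plus pyruvate carboxylase: "
                            "pyruvate -> 2 acetyl-CoA",
    "Glycolysis_GAP_to_OAA": "lower glycolysis + PEP carboxylase: GAP -> oxaloacetate",
    "Gluconeo_OAA_to_GAP": "gluconeogenesis: oxaloacetate -> GAP",
}


@dataclass(frozen=True)
class PathwayEntry:
    """A pathway or connecting module: model fragment plus flux distribution."""

    name: str
    model_fragment: NetworkModel
    flux: FluxDistribution
    product: str
    provenance: str = ""

    @property
    def net(self) -> dict[str, float]:
        """Net stoichiometry under the entry's flux distribution."""
        return net_stoichiometry(self.model_fragment, self.flux)

    @property
    def normalized_net(self) -> dict[str, float]:
        """Net stoichiometry scaled so the product coefficient is +1."""
        net = self.net
        scale = net[self.product]
        if scale <= 0:
            raise ValueError(f"{self.name}: product {self.product!r} is not net-produced")
        return {mid: coeff / scale for mid, coeff in net.items()}


def _data_dir() -> Path:
    return Path(resources.files("pathcost.pathways") / "data")


def list_pathways() -> list[str]:
    """Names of all registered pathways and modules."""
    return sorted(p.stem for p in _data_dir().glob("*.tsv"))


def get_pathway(name: str) -> PathwayEntry:
    """Load a registered pathway; raises listing the registry on a bad name."""
    path = _data_dir() / f"{name}.tsv"
    if not path.exists():
        raise KeyError(
            f"unknown pathway {name!r}; registered: {', '.join(list_pathways())}"
        )
    model, flux = read_pathway_tables(path)
    entry = PathwayEntry(
        name=name,
        model_fragment=model,
        flux=flux,
        product=flux.product,
        provenance=_PROVENANCE.get(name, ""),
    )
    report = validate_flux(model, flux)
    if not report.passed:  # pragma: no cover - fixtures are validated by tests
        raise ValueError(f"pathway fixture {name} fails steady state: {report.imbalances}")
    return entry


def compose(
    core: PathwayEntry, module: PathwayEntry, target_product: str
) -> PathwayEntry:
    """Combine a core pathway with a connecting module consuming its product.

    The module's fluxes are scaled so the core's product cancels exactly;
    the combined entry is normalized to produce one unit of
    ``target_product`` per unit pathway flux.  Reaction ids colliding
    between the two fragments get the module name as a prefix.
    """
    if not module.flux.fluxes:
        return PathwayEntry(
            name=core.name,
            model_fragment=core.model_fragment,
            flux=core.flux,
            product=target_product if target_product in core.net else core.product,
            provenance=core.provenance,
        )
    core_net = core.net
    mod_net = module.net
    produced = core_net.get(core.product, 0.0)
    consumed = -mod_net.get(core.product, 0.0)
    if produced <= 0 or consumed <= 0:
        raise ValueError(
            f"cannot compose {core.name} with {module.name}: module does not "
            f"consume the core product {core.product!r}"
        )
    scale = produced / consumed
    target_out = scale * mod_net.get(target_product, 0.0) + core_net.get(target_product, 0.0)
    if target_out <= 0:
        raise ValueError(
            f"composition of {core.name} and {module.name} does not net-produce "
            f"{target_product!r}"
        )

    core_rids = set(core.model_fragment.reaction_ids)
    renamed = {}
    reactions = list(core.model_fragment.reactions)
    for r in module.model_fragment.reactions:
        rid = r.id
        if rid in core_rids:
            rid = f"{module.name}__{r.id}"
            renamed[r.id] = rid
            r = type(r)(
                id=rid, stoichiometry=dict(r.stoichiometry), enzyme_mass=r.enzyme_mass,
                z_protons=r.z_protons, keq=r.keq, keq_gsd=r.keq_gsd,
            )
        reactions.append(r)

    mets: dict[str, Metabolite] = {m.id: m for m in core.model_fragment.metabolites}
    for m in module.model_fragment.metabolites:
        mets.setdefault(m.id, m)
    # the shared intermediate becomes internal in the composite, the new
    # target product must be exchangeable
    def _with_role(m: Metabolite, role: str) -> Metabolite:
        return Metabolite(
            id=m.id, name=m.name, role=role, default_bounds=m.default_bounds,
            carbon_count=m.carbon_count, electron_count=m.electron_count,
        )

    if target_product != core.product:
        mets[core.product] = _with_role(mets[core.product], "internal")
    if mets[target_product].role == "internal":
        mets[target_product] = _with_role(mets[target_product], "exchanged")

    norm = 1.0 / target_out
    fluxes = {rid: v * norm for rid, v in core.flux.fluxes.items()}
    for rid, v in module.flux.fluxes.items():
        fluxes[renamed.get(rid, rid)] = v * scale * norm

    model = NetworkModel(metabolites=tuple(mets.values()), reactions=tuple(reactions))
    flux = FluxDistribution(
        name=f"{core.name}+{module.name}",
        fluxes=fluxes,
        product=target_product,
        product_rate=1.0,
    )
    report = validate_flux(model, flux)
    if not report.passed:
        raise ValueError(
            f"composition {core.name}+{module.name} leaves internal imbalances: "
            f"{report.imbalances}"
        )
    return PathwayEntry(
        name=flux.name,
        model_fragment=model,
        flux=flux,
        product=target_product,
        provenance=f"{core.provenance}; composed with {module.provenance}",
    )
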