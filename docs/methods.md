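# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `pathcost`, in the order the pipeline runs them.

## Units and conventions

Concentrations are molar everywhere internally (file columns may declare
mM/µM and are converted on read). Fluxes are mM·s⁻¹, enzyme masses kDa
(= mg·µmol⁻¹), so enzyme cost comes out in mg·mL⁻¹ and specific activity
in µmol·min⁻¹·mg⁻¹. Equilibrium constants are transformed constants at the
model's implicit pH with a 1 M standard state; water and protons are
omitted from stoichiometries because their effect is folded into the
transformed K_eq inputs. Stoichiometric coefficients are exact rationals
(products positive); reaction orientation encodes direction so all pathway
fluxes are nonnegative.

## Thermodynamics

Driving force: θ = ln K_eq − Σᵢ nᵢxᵢ with x = ln(c/M); ΔG′ = −RT·θ.
Defaults: T = 298.15 K (RT = 2.479 kJ/mol); the temperature underlying the
input K_eq values is taken as 25 °C — an assumption, stated rather than
derived, since equilibrium data are commonly tabulated at that reference.
Membrane potential Δψ = −150 mV; proton-translocating reactions adjust
K_eq′ = K_eq·exp(zFΔψ/RT) with z > 0 for cytosol→periplasm transport, so a
reductive reaction importing 2 protons (z encoded on the written direction)
gains roughly a factor 1.2·10⁵ at these defaults. No pH or ionic-strength
transforms are computed.

Feasibility uses the max–min driving force: maximize m subject to
θⱼ(x) ≥ m for all active reactions and ln lb ≤ x ≤ ln ub, a linear program
solved with HiGHS. The pathway is usable by ECM iff m > 0; the optimal x
also serves as the ECM starting point because every cost term is finite
there.

## Parameter balancing

Per reaction (reactions are balanced independently), the unknowns are
q = (ln kcat⁺, ln kcat⁻, ln K_M per participant). The estimate minimizes

    Σ_priors ((qᵢ − ln medianᵢ)/ln gsdᵢ)² + Σ_records ((a·q − ln value)/ln gsd)²

subject to the Haldane equality c·q = ln K_eq, with K_eq never adjusted.
Priors: kcat median 10 s⁻¹ (gsd 10), K_M median 0.1 mM (gsd 10) — round
literature-scale defaults, fully configurable. Two deliberate modeling
choices:

* **No independent prior on kcat⁻.** With K_eq fixed, a second kcat prior
  would double-count prior information against the constraint; the
  established balancing approach avoids the same problem by parametrizing
  rate constants through a geometric-mean velocity constant. Here kcat⁻ is
  determined by the constraint, its own measurement when one exists, and
  the other priors through the constraint. Consequence: with no data at
  all, a K_eq = 100 reaction yields kcat⁺ = 10 s⁻¹, kcat⁻ = 0.1 s⁻¹ and
  K_M at the prior medians.
* **Hard constraint, exact solve.** The KKT system of the constrained
  quadratic is solved directly; the posterior covariance is the upper-left
  block of the inverse KKT matrix (well-defined even though kcat⁻ alone is
  unpenalized). Posterior geometric SDs are exp of the square-rooted
  diagonal. Measurement gsds of exactly 1 are floored at 1.001 to keep
  weights finite.

Inconsistent data (typically both rate constants measured) are handled by
the inflation loop: after each balance, if any balanced parameter deviates
from a measurement by more than 3 posterior geometric SDs, all record and
prior gsds are widened by factor 1.5 on the log scale and balancing
repeats (at most 10 rounds, then an error carries the worst residual).
With a hard equality the Haldane relationship always holds; the 3-gsd rule
is the implementable reading of "inflate until consistent" — balanced
values must not be absurdly far from what was measured.

## Enzyme cost minimization

Enzyme demand per reaction: E = (v/kcat⁺)·η_rev⁻¹·η_sat⁻¹ with
η_rev = 1 − e^(−θ) and the common modular (CM) rate-law saturation factor
η_sat = ∏_S s^m / (∏_S (1+s)^m + ∏_P (1+p)^m − 1), s = c/K_M over
substrates, p over products. The CM law is the framework default; it is
isolated behind `saturation_factor` so alternative rate laws can be added.
The objective Σⱼ Mⱼ Eⱼ is convex in x.

Optimization: fixed species (lower = upper bound) are substituted out;
free log-concentrations are optimized with L-BFGS-B inside the box from
the max–min driving-force point plus 5 random interior restarts
(seed 0 by default; deterministic given the seed), followed by one
Nelder-Mead polish. The optimizer works on ln(cost) — same minimizer,
compressed dynamic range. Thermodynamically infeasible points return a
penalty growing with the violation, which keeps iterates feasible since
the cost diverges as any θ → 0⁺. Agreement with an exhaustive grid oracle
(30 points per free dimension, one refinement pass) is part of the test
suite and of `scripts/acceptance.py`.

Monte-Carlo uncertainty: every kinetic parameter is multiplied by a
lognormal deviate with its posterior gsd, the Haldane relationship is
re-imposed by re-balancing the perturbed values as data (K_eq fixed), ECM
re-runs, and the geometric mean and geometric SD over the iterations
(default 100) are reported. Infeasible iterations are dropped; more than
50% drops abort.

Fixed cofactor pools (molar) for the comparison pipeline: ATP 5·10⁻³,
ADP 5·10⁻⁴, AMP 2·10⁻⁴, Pi 10⁻², PPi 10⁻³, NAD⁺ 10⁻³, NADH 10⁻⁴,
NADP⁺ 1.2·10⁻⁵, NADPH 1.2·10⁻⁴ (NADPH pool more reduced than NADH, as in
most bacteria), quinones 10⁻³, CoA 10⁻³. Scenarios clamp inorganic carbon:
*atmospheric* CO2 10 µM / HCO3⁻ 100 µM (air-saturated water, carbonate in
equilibrium near pH 7.5); *bioreactor* 100-fold higher. Other metabolites
default to 1 µM–10 mM.

## ATP ledger and yields

Direct ATP count: ADP-forming hydrolysis 1, AMP-forming 2 (two ATP
equivalents regenerate AMP). ATP-equivalent cost additionally values
cofactor turnover at optimal aerobic respiration: NADH 2.5, quinol
(ubi-/menaquinol, FADH2) 1.5, NADPH 2.75 (= NADH + 0.25 for the membrane
transhydrogenase at H⁺/ATP = 4). Produced reduced cofactors credit the
ledger at the same flat values. Menaquinol is valued like ubiquinol;
double counting with the transmembrane K_eq adjustment is avoided by
valuing quinols only in net stoichiometries, never inside ECM. The
H⁺/ATP ratio is fixed at 4 — chloroplast-type 4.67 or 3.3 stoichiometries
are out of scope, so all projected costs are optimistic estimates.

Yields on a donor: total demand = donor molecules incorporated as carbon
plus ATP-equivalent cost divided by the energy one donor delivers
(nadh_per_donor · 2.5 + atp_per_donor); yield = 1/demand. Default donors:
formate 1 NADH; methanol 3 NADH (NAD route) or 1 ATP + 2 NADH (PQQ route);
H2 1 NADH, no carbon. The PQQ/NAD methanol splits are defaults to be
checked against a specific organism's electron chain before quantitative
use.

## Pathway registry

Pathways are encoded at the granularity of published pathway maps, lumping
multi-step arrows except where a printed ATP/yield number requires the
split (e.g. ADP- vs AMP-forming CoA ligases distinguish the thaumarchaeal
and crenarchaeal 3-HP/4-HB variants; the phosphotransferase reactions
replace both phosphatases and two of the three phosphoribulokinase ATP
inputs in the phosphatase-less CBB variant). Every fixture carries carbon
and electron counts per metabolite (4C + H − 2O relative to
CO2/H2O/phosphate; 2 e⁻ per NAD(P)H or quinol), and every reaction is
individually carbon- and electron-balanced — this is enforced by tests.

The malyl-CoA/glycerate-type cycles: the variant using the
β-hydroxyaspartate cycle for glyoxylate assimilation and pyruvate
carboxylase for pyruvate entry needs 3 ATP per 2 acetyl-CoA; the original
glycerate-route variant (glyoxylate carboligase/glycerate dehydrogenase,
glycerate kinase, PEP-synthase entry) needs 5 — the two swaps together
account for the 1-ATP-per-acetyl-CoA difference between the designs.

Per-reaction K_eq (10³) and enzyme masses (100 kDa) in the fixtures are
synthetic placeholders, sufficient for stoichiometric analyses and clearly
marked in the files; the curated 113-reaction kinetic dataset is not
redistributed, so full-dataset activity numbers (e.g. the CBB cycle near
0.25 µmol·min⁻¹·mg⁻¹ at atmospheric CO2) can only be reproduced after
placing that dataset under `data/curated/`.

## Synthetic benchmark — what it shows and what it does not

The generator samples ln kcat⁺ and ln K_M from the priors and derives
kcat⁻ from the Haldane relationship exactly; observations multiply each
parameter by lognormal noise (default gsd 1.5) and drop it with
probability 0.3 — the noise level and missingness chosen to resemble a
curated literature compilation. Noise is independent across parameters,
whereas real assay errors correlate within a study; toy networks are
unbranched chains so the brute-force oracle stays ≤ 3-dimensional; and
truth being drawn from the balancing priors means prior misspecification
is untested. Passing the benchmark therefore demonstrates correctness of
the estimator, optimizer and bookkeeping under the assumed statistical
model — not predictive accuracy on curated enzyme data.

Benchmark sizes (chosen to characterize behaviour at desk scale): 200
reactions for Haldane-residual and parameter-recovery statistics, 50
(tests) / 20 (acceptance script) toy networks for optimizer-vs-oracle
agreement, 20–100 Monte-Carlo iterations.

## Known limitations

* One reaction balanced at a time; no joint multi-reaction balancing with
  shared formation energies, no sampling-based posteriors.
* Enzyme cost weights are molecular masses only; no allosteric regulation,
  metabolite toxicity, or vitamin-B12 synthesis cost.
* Flux distributions are inputs, not optimized.
* The registry's placeholder kinetics make cross-pathway *activity*
  comparisons meaningful only once curated kinetics are supplied; ATP
  counts, electron balances and yields are exact regardless.
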