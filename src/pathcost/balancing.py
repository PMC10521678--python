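"""Parameter balancing: complete, Haldane-consistent kinetics per reaction.

Each reaction is balanced alone.  The unknown vector is

    q = (ln kcat+, ln kcat-, ln Km_1, ..., ln Km_s)

over all participants.  Lognormal priors and lognormal measurements enter a
weighted least-squares objective

    sum_priors ((q_i - ln median_i) / ln gsd_i)^2
    + sum_records ((a_r . q - ln value_r) / ln gsd_r)^2

minimized subject to one linear equality encoding the Haldane relationship

    ln Keq = ln kcat+ - ln kcat- + sum_P m_P ln Km_P - sum_S m_S ln Km_S

with the equilibrium constant held fixed (never adjusted).  Prior terms
cover ln kcat+ and every ln Km; the backward rate constant carries no
independent prior — it is determined by the Haldane constraint (and by
its own measurement where one exists).  Placing a second, independent
kcat prior would double-count prior information against the fixed Keq;
the established balancing approach avoids this the same way by
parametrizing rate constants through a geometric-mean velocity constant.

The exact minimizer is obtained from the KKT linear system; posterior
geometric standard deviations come from the diagonal of the constrained
posterior covariance (the upper-left block of the inverse KKT matrix,
well-defined even though the unconstrained problem leaves kcat-
unpenalized).

When measurements contradict the equilibrium constant (typically when both
rate constants were measured), all measurement and prior uncertainties are
inflated iteratively until the balanced values sit within 3 posterior
geometric standard deviations of every measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ParameterRecord, Reaction

__all__ = [
    "PriorSpec",
    "BalancedKinetics",
    "BalancingProblem",
    "assemble_problem",
    "balance_reaction",
    "inflate_until_consistent",
    "check_haldane",
    "HALDANE_TOL",
]

#: Absolute tolerance on the log-scale Haldane residual of balanced output.
HALDANE_TOL = 1e-6

#: Smallest usable log-uncertainty; a gsd of exactly 1 would give an
#: infinite weight, so sigmas are floored here.
_MIN_LOG_GSD = math.log(1.001)


@dataclass(frozen=True)
class PriorSpec:
    """Lognormal priors for rate and Michaelis constants.

    Defaults are round literature-scale values: kcat median 10 1/s, Km
    median 0.1 mM, both with a geometric standard deviation of 10.
    """

    kcat_median: float = 10.0
    kcat_gsd: float = 10.0
    km_median: float = 1e-4
    km_gsd: float = 10.0

    def __post_init__(self) -> None:
        if self.kcat_median <= 0 or self.km_median <= 0:
            raise ValueError("prior medians must be > 0")
        if self.kcat_gsd <= 1 or self.km_gsd <= 1:
            raise ValueError("prior gsds must be > 1")

    def scaled(self, factor: float) -> "PriorSpec":
        """Priors with both geometric spreads widened by ``factor``."""
        return PriorSpec(
            kcat_median=self.kcat_median,
            kcat_gsd=math.exp(math.log(self.kcat_gsd) * factor),
            km_median=self.km_median,
            km_gsd=math.exp(math.log(self.km_gsd) * factor),
        )


@dataclass(frozen=True)
class BalancedKinetics:
    """A complete Haldane-consistent kinetic parameter set for one reaction.

    ``posterior_gsd`` maps parameter names (``"kcat_forward"``,
    ``"kcat_backward"``, ``"km:<compound>"``) to geometric standard
    deviations of the posterior.
    """

    reaction_id: str
    kcat_forward: float
    kcat_backward: float
    km: dict[str, float]
    keq: float
    posterior_gsd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.kcat_forward, self.kcat_backward, self.keq) <= 0:
            raise ValueError(f"{self.reaction_id}: kinetic values must be > 0")
        if any(v <= 0 for v in self.km.values()):
            raise ValueError(f"{self.reaction_id}: Km values must be > 0")


@dataclass
class BalancingProblem:
    """A constrained weighted least-squares problem in log space.

    ``names`` orders the unknowns; rows of ``A`` with targets ``y`` and
    log-uncertainties ``sigma`` collect prior and data terms; ``c . q =
    rhs`` is the Haldane equality.
    """

    reaction_id: str
    names: list[str]
    A: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    c: np.ndarray
    rhs: float
    keq: float


def _unknown_names(reaction: Reaction) -> list[str]:
    return ["kcat_forward", "kcat_backward"] + [
        f"km:{mid}" for mid in reaction.stoichiometry
    ]


def _haldane_coefficients(reaction: Reaction, names: list[str]) -> np.ndarray:
    c = np.zeros(len(names))
    c[names.index("kcat_forward")] = 1.0
    c[names.index("kcat_backward")] = -1.0
    for mid, coeff in reaction.stoichiometry.items():
        # products positive: +m_P ln K_P, substrates: -m_S ln K_S
        c[names.index(f"km:{mid}")] = float(coeff)
    return c


def assemble_problem(
    reaction: Reaction,
    records: list[ParameterRecord],
    priors: PriorSpec,
) -> BalancingProblem:
    """Build the constrained least-squares problem for one reaction.

    ln kcat+ and every ln Km receive a prior term (kcat- is determined by
    the Haldane constraint, see the module docstring); every record adds a
    data term with a unit coefficient on its unknown.  Records of quantity
    ``keq`` are ignored — the equilibrium constant is fixed from the
    reaction itself.
    """
    if not reaction.substrates or not reaction.products:
        raise ValueError(
            f"reaction {reaction.id}: Haldane relationship undefined without "
            "both substrates and products"
        )
    names = _unknown_names(reaction)
    rows: list[np.ndarray] = []
    y: list[float] = []
    sigma: list[float] = []

    def _term(name: str, value: float, gsd: float) -> None:
        a = np.zeros(len(names))
        a[names.index(name)] = 1.0
        rows.append(a)
        y.append(math.log(value))
        sigma.append(max(math.log(gsd), _MIN_LOG_GSD))

    for name in names:
        if name.startswith("km:"):
            _term(name, priors.km_median, priors.km_gsd)
        elif name == "kcat_forward":
            _term(name, priors.kcat_median, priors.kcat_gsd)
    for rec in records:
        if rec.reaction_id != reaction.id:
            raise ValueError(
                f"record for {rec.reaction_id!r} passed to reaction {reaction.id!r}"
            )
        if rec.quantity == "keq":
            continue
        name = rec.quantity if rec.quantity != "km" else f"km:{rec.compound}"
        if name not in names:
            raise ValueError(
                f"record ({rec.reaction_id}, {rec.quantity}, {rec.compound}) "
                "does not match any unknown"
            )
        _term(name, rec.value, rec.gsd)

    return BalancingProblem(
        reaction_id=reaction.id,
        names=names,
        A=np.vstack(rows),
        y=np.asarray(y),
        sigma=np.asarray(sigma),
        c=_haldane_coefficients(reaction, names),
        rhs=math.log(reaction.keq),
        keq=reaction.keq,
    )


def _solve(problem: BalancingProblem) -> tuple[np.ndarray, np.ndarray]:
    """Exact minimizer and posterior covariance of the constrained QP."""
    w = 1.0 / problem.sigma**2
    P = (problem.A * w[:, None]).T @ problem.A
    r = (problem.A * w[:, None]).T @ problem.y
    n = len(problem.names)
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = P
    K[:n, n] = problem.c
    K[n, :n] = problem.c
    rhs = np.append(r, problem.rhs)
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by priors
        raise RuntimeError(
            f"singular KKT system for reaction {problem.reaction_id}"
        ) from exc
    q = sol[:n]
    # constrained posterior covariance: upper-left block of the inverse
    # KKT matrix (valid even when P alone is singular, e.g. an unmeasured
    # kcat- determined only by the constraint)
    cov_constrained = np.linalg.inv(K)[:n, :n]
    return q, cov_constrained


def balance_reaction(
    reaction: Reaction,
    records: list[ParameterRecord],
    priors: PriorSpec | None = None,
) -> BalancedKinetics:
    """MAP estimate of the full kinetic set under the Haldane constraint.

    Returns the exact minimizer of the constrained quadratic objective;
    the output satisfies the Haldane relationship to ``HALDANE_TOL`` and
    carries posterior geometric standard deviations per parameter.
    """
    priors = priors or PriorSpec()
    problem = assemble_problem(reaction, records, priors)
    q, cov = _solve(problem)
    values = {name: float(v) for name, v in zip(problem.names, np.exp(q))}
    gsds = {
        name: math.exp(math.sqrt(max(cov[i, i], 0.0)))
        for i, name in enumerate(problem.names)
    }
    bk = BalancedKinetics(
        reaction_id=reaction.id,
        kcat_forward=values["kcat_forward"],
        kcat_backward=values["kcat_backward"],
        km={
            name.split(":", 1)[1]: val
            for name, val in values.items()
            if name.startswith("km:")
        },
        keq=reaction.keq,
        posterior_gsd=gsds,
    )
    residual = check_haldane(bk, reaction)
    if abs(residual) > HALDANE_TOL:  # pragma: no cover - sanity guard
        raise RuntimeError(
            f"balance_reaction({reaction.id}): Haldane residual {residual:.3g} "
            f"exceeds {HALDANE_TOL}"
        )
    return bk


def check_haldane(bk: BalancedKinetics, reaction: Reaction) -> float:
    """Signed log-scale Haldane residual.

    Zero iff Keq = kcat+ prod_P Km_P^m_P / (kcat- prod_S Km_S^m_S);
    positive when the kinetic side overshoots Keq (e.g. multiplying kcat+
    by e raises the residual by 1).
    """
    kinetic = math.log(bk.kcat_forward) - math.log(bk.kcat_backward)
    for mid, coeff in reaction.stoichiometry.items():
        kinetic += float(coeff) * math.log(bk.km[mid])
    return kinetic - math.log(bk.keq)


@dataclass(frozen=True)
class InflationResult:
    kinetics: BalancedKinetics
    rounds: int


def inflate_until_consistent(
    reaction: Reaction,
    records: list[ParameterRecord],
    priors: PriorSpec | None = None,
    inflate_factor: float = 1.5,
    max_iter: int = 10,
) -> InflationResult:
    """Balance, inflating all uncertainties until measurements are honored.

    After each balancing pass, if any balanced parameter deviates from a
    measured record by more than 3 posterior geometric standard deviations,
    every record and prior gsd is widened by ``inflate_factor`` (on the log
    scale) and balancing repeats, at most ``max_iter`` times.  Consistent
    data therefore take 0 inflation rounds.
    """
    if inflate_factor <= 1:
        raise ValueError("inflate_factor must be > 1")
    priors = priors or PriorSpec()
    current_records = list(records)
    current_priors = priors
    worst = math.inf
    for rounds in range(max_iter + 1):
        bk = balance_reaction(reaction, current_records, current_priors)
        worst = 0.0
        for rec in current_records:
            if rec.quantity == "keq":
                continue
            name = rec.quantity if rec.quantity != "km" else f"km:{rec.compound}"
            balanced = {
                "kcat_forward": bk.kcat_forward,
                "kcat_backward": bk.kcat_backward,
            }.get(name, bk.km.get(name.split(":", 1)[1]) if name.startswith("km:") else None)
            dev = abs(math.log(balanced) - math.log(rec.value))
            limit = 3.0 * max(math.log(bk.posterior_gsd[name]), _MIN_LOG_GSD)
            worst = max(worst, dev - limit)
        if worst <= 0:
            return InflationResult(kinetics=bk, rounds=rounds)
        current_records = [
            ParameterRecord(
                reaction_id=rec.reaction_id,
                quantity=rec.quantity,
                value=rec.value,
                gsd=math.exp(math.log(max(rec.gsd, 1.001)) * inflate_factor),
                compound=rec.compound,
            )
            for rec in current_records
        ]
        current_priors = current_priors.scaled(inflate_factor)
    raise RuntimeError(
        f"inflate_until_consistent({reaction.id}): still inconsistent after "
        f"{max_iter} rounds (worst excess deviation {worst:.3g} log units)"
    )
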