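"""Linear-programming core: FBA, flux variability and product yields.

The stoichiometric system is the standard steady-state formulation
``S v = 0`` with elementwise flux bounds ``v_min <= v <= v_max`` and a linear
objective ``Z = c v`` (usually the biomass flux, i.e. the growth rate).
Solving is delegated to scipy's HiGHS backend; ``enumerate_optimum`` provides
an exhaustive vertex-enumeration cross-check for tiny systems that is fully
independent of the LP solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel

__all__ = [
    "StoichiometricSystem",
    "FluxSolution",
    "build_system",
    "solve_fba",
    "fba",
    "flux_variability",
    "max_product_yield",
    "zero_flux_set",
    "enumerate_optimum",
    "FEASIBILITY_TOL",
]

#: maximal allowed steady-state residual ||S v||_inf of an optimal solution
FEASIBILITY_TOL = 1e-6


@dataclass
class StoichiometricSystem:
    S: np.ndarray  # metabolites x reactions
    lower: np.ndarray
    upper: np.ndarray
    c: np.ndarray  # objective row (1 on the biomass column)
    reaction_ids: list[str]
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if not (len(self.lower) == len(self.upper) == len(self.c) == n == len(self.reaction_ids)):
            raise ValueError("system dimensions disagree")
        if len(self.metabolite_ids) != m:
            raise ValueError("system dimensions disagree")
        if np.any(self.lower > self.upper):
            raise ValueError("unordered bounds")

    def column(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    def copy(self) -> "StoichiometricSystem":
        return StoichiometricSystem(
            self.S.copy(), self.lower.copy(), self.upper.copy(), self.c.copy(),
            list(self.reaction_ids), list(self.metabolite_ids),
        )


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    Z: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def growth(self) -> float:
        """Objective value with non-optimal statuses mapped to zero growth."""
        return self.Z if self.optimal else 0.0


def build_system(model: MetabolicModel) -> StoichiometricSystem:
    """Assemble ``S``, bounds and objective with deterministic sorted ordering.

    Every declared metabolite that appears in a reaction gets a balancing
    row; exchange reactions carry their single metabolite with coefficient
    -1, so no extra boundary species row is created.
    """
    rids = sorted(model.reactions)
    used = sorted({m for r in model.reactions.values() for m in r.stoichiometry})
    row = {m: i for i, m in enumerate(used)}
    S = np.zeros((len(used), len(rids)))
    lower = np.empty(len(rids))
    upper = np.empty(len(rids))
    c = np.zeros(len(rids))
    for j, rid in enumerate(rids):
        rxn = model.reactions[rid]
        for m, coef in rxn.stoichiometry.items():
            S[row[m], j] = coef
        lower[j] = rxn.lower_bound
        upper[j] = rxn.upper_bound
    c[rids.index(model.objective_id)] = 1.0
    return StoichiometricSystem(S, lower, upper, c, rids, used)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(S, lower, upper, c, sense=-1.0, extra_ub=None):
    """linprog wrapper; sense=-1 maximizes c v."""
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub, b_ub = extra_ub
    res = linprog(
        sense * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lower, upper)),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    x = res.x if res.x is not None else np.zeros(S.shape[1])
    return status, x


def solve_fba(system: StoichiometricSystem) -> FluxSolution:
    """Maximize ``c v`` subject to ``S v = 0`` and the flux bounds.

    Infeasible systems are reported as such (downstream code treats them as
    zero growth); an unbounded objective signals a model defect such as an
    unconstrained energy-generating cycle.
    """
    status, x = _solve(system.S, system.lower, system.upper, system.c)
    Z = float(system.c @ x) if status == "optimal" else float("nan")
    return FluxSolution(
        status=status,
        Z=Z if status == "optimal" else (float("inf") if status == "unbounded" else 0.0),
        fluxes=dict(zip(system.reaction_ids, x.tolist())),
    )


def fba(model: MetabolicModel) -> FluxSolution:
    return solve_fba(build_system(model))


def flux_variability(
    system: StoichiometricSystem,
    reaction_ids: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux range at ``Z >= fraction_of_optimum * Z*``."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    base = solve_fba(system)
    if not base.optimal:
        raise ValueError(f"base FBA problem is {base.status}; FVA undefined")
    # c v >= f Z*  encoded as  -c v <= -f Z*
    extra = (-system.c[None, :], np.array([-fraction_of_optimum * base.Z]))
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids if reaction_ids is not None else system.reaction_ids:
        j = system.column(rid)
        e = np.zeros(len(system.c))
        e[j] = 1.0
        _, xmin = _solve(system.S, system.lower, system.upper, e, sense=1.0, extra_ub=extra)
        _, xmax = _solve(system.S, system.lower, system.upper, e, sense=-1.0, extra_ub=extra)
        lo, hi = float(xmin[j]), float(xmax[j])
        out[rid] = (min(lo, hi), max(lo, hi))
    return out


def max_product_yield(
    model: MetabolicModel,
    product_exchange: str,
    substrate_exchange: str,
    growth_fraction: float = 0.0,
) -> float:
    """Maximum molar yield (mol product secreted per mol substrate taken up).

    Product secretion is maximized by LP; the yield divides the product flux
    by the realized substrate uptake. By default no growth is demanded;
    ``growth_fraction`` > 0 additionally requires the biomass flux to stay at
    that fraction of its optimum (a growth-coupled yield).
    """
    for ex in (product_exchange, substrate_exchange):
        if ex not in model.reactions or model.reactions[ex].kind != "exchange":
            raise ValueError(f"{ex!r} is not an exchange reaction of the model")
    sub = model.reactions[substrate_exchange]
    if not np.isfinite(sub.lower_bound) or sub.lower_bound >= 0:
        raise ValueError(
            f"substrate exchange {substrate_exchange!r} must allow a finite "
            "nonzero uptake (negative lower bound)"
        )
    system = build_system(model)
    extra = None
    if growth_fraction > 0.0:
        base = solve_fba(system)
        if not base.optimal or base.Z <= 0:
            raise ValueError("growth-coupled yield requires a growing model")
        extra = (-system.c[None, :], np.array([-growth_fraction * base.Z]))
    e = np.zeros(len(system.c))
    e[system.column(product_exchange)] = 1.0
    status, x = _solve(system.S, system.lower, system.upper, e, sense=-1.0, extra_ub=extra)
    if status != "optimal":
        return 0.0
    v_prod = float(x[system.column(product_exchange)])
    v_sub = float(x[system.column(substrate_exchange)])
    if v_prod <= FEASIBILITY_TOL or v_sub >= -FEASIBILITY_TOL:
        return 0.0
    return v_prod / -v_sub


def zero_flux_set(
    model: MetabolicModel, fraction_of_optimum: float = 1.0, tol: float = FEASIBILITY_TOL
) -> set[str]:
    """Reactions that carry no flux in any optimal flux distribution.

    Defined via FVA (min = max = 0 at the given fraction of the optimum) so
    the answer is well defined under degenerate optima — stricter than
    inspecting a single LP solution.
    """
    system = build_system(model)
    ranges = flux_variability(system, fraction_of_optimum=fraction_of_optimum)
    return {rid for rid, (lo, hi) in ranges.items() if abs(lo) <= tol and abs(hi) <= tol}


# ---------------------------------------------------------------------------
# exhaustive cross-check for tiny systems
# ---------------------------------------------------------------------------

def enumerate_optimum(system: StoichiometricSystem, max_reactions: int = 8):
    """Objective optimum by brute-force vertex enumeration.

    Enumerates every basic feasible solution of the polytope
    ``{v : S v = 0, l <= v <= u}``: each subset of variables is fixed to a
    bound (every lower/upper combination), the remainder solved from the
    equality system and kept when that solution is unique and within bounds.
    Returns the best objective value, or None when no vertex is feasible.
    Intended as an independent oracle for systems of a handful of reactions;
    cost grows as 3^n.
    """
    n = len(system.reaction_ids)
    if n > max_reactions:
        raise ValueError(f"enumeration limited to {max_reactions} reactions")
    S, lo, hi, c = system.S, system.lower, system.upper, system.c
    best = None
    for fixed_mask in itertools.product((0, 1), repeat=n):
        fixed = [j for j in range(n) if fixed_mask[j]]
        free = [j for j in range(n) if not fixed_mask[j]]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # not a vertex: free part underdetermined
        for sides in itertools.product((0, 1), repeat=len(fixed)):
            v = np.zeros(n)
            for j, side in zip(fixed, sides):
                v[j] = hi[j] if side else lo[j]
            if not np.all(np.isfinite(v[fixed])):
                continue
            if free:
                rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > 1e-7:
                continue
            if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
                continue
            z = float(c @ v)
            if best is None or z > best:
                best = z
    return best
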