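"""Flux balance analysis for auditing models before/after standardization.

Maximises an objective flux subject to steady-state mass balance
``S·v = 0`` and box bounds on each flux.  Default bounds are
(−1000, 1000) for reversible and (0, 1000) for irreversible reactions.
The model keeps exact rational stoichiometry; floats appear only inside
the HiGHS solver, and optima are reported to a 1e−6 mass-balance
tolerance.

Re-balancing a published model can *lower* its FBA optimum: repaired
stoichiometry (typically added protons) imposes real costs the sloppy
version evaded.  :func:`standardization_delta` quantifies that relative
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .model import Model

TOLERANCE = 1e-6
DEFAULT_BOUND = 1000.0


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float] = None
    fluxes: dict[str, float] = field(default_factory=dict)


def stoichiometric_matrix(m: Model) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense S (metabolite x reaction) plus row and column orderings."""
    met_ids = sorted(m.metabolites)
    rxn_ids = sorted(m.reactions)
    midx = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for p in m.reactions[rid].participants:
            S[midx[p.metabolite], j] += float(p.coefficient)
    return S, met_ids, rxn_ids


def _bounds_for(m: Model, rid: str) -> tuple[float, float]:
    if rid in m.bounds:
        return m.bounds[rid]
    from .model import Direction

    if m.reactions[rid].direction is Direction.REVERSIBLE:
        return (-DEFAULT_BOUND, DEFAULT_BOUND)
    return (0.0, DEFAULT_BOUND)


def maximize_objective(m: Model, objective: Optional[str] = None) -> FluxResult:
    """Solve max c·v s.t. S·v = 0, lb <= v <= ub (HiGHS).

    ``objective`` overrides the model's objective reaction.  Solver
    failure is surfaced as status infeasible/unbounded, never silently.
    """
    obj = objective or m.objective
    if obj is None:
        raise ValueError("model has no objective reaction")
    if obj not in m.reactions:
        raise ValueError(f"objective {obj!r} is not a reaction id")
    m.validate()
    S, met_ids, rxn_ids = stoichiometric_matrix(m)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(obj)] = -1.0  # linprog minimises
    bounds = [_bounds_for(m, rid) for rid in rxn_ids]
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    if res.status == 3:
        return FluxResult(status="unbounded")
    if res.status != 0:
        return FluxResult(status="infeasible")
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    return FluxResult(status="optimal", objective_value=-float(res.fun), fluxes=fluxes)


@dataclass
class StandardizationDelta:
    """Relative objective change caused by standardization/repair."""

    delta: Optional[float]  # (obj_std - obj_src) / obj_src; None if undefined
    objective_source: Optional[float]
    objective_standardized: Optional[float]
    undefined: bool = False
    repairs: dict[str, str] = field(default_factory=dict)


def standardization_delta(
    source: Model,
    standardized: Model,
    repairs: Optional[dict[str, str]] = None,
) -> StandardizationDelta:
    """(obj_std − obj_src)/obj_src for two solvable models.

    A zero source optimum makes the relative change undefined; that is
    flagged rather than raised, since an audit report must still render.
    """
    src = maximize_objective(source)
    std = maximize_objective(standardized)
    if src.status != "optimal" or std.status != "optimal":
        raise ValueError(
            f"both models must solve to optimality (got {src.status}/{std.status})"
        )
    if abs(src.objective_value) < TOLERANCE:
        return StandardizationDelta(
            delta=None,
            objective_source=src.objective_value,
            objective_standardized=std.objective_value,
            undefined=True,
            repairs=repairs or {},
        )
    delta = (std.objective_value - src.objective_value) / src.objective_value
    return StandardizationDelta(
        delta=delta,
        objective_source=src.objective_value,
        objective_standardized=std.objective_value,
        repairs=repairs or {},
    )


def mass_balance_residual(m: Model, fluxes: dict[str, float]) -> float:
    """max_i |S·v|_i — should be <= 1e-6 at any reported optimum."""
    S, met_ids, rxn_ids = stoichiometric_matrix(m)
    v = np.array([fluxes.get(rid, 0.0) for rid in rxn_ids])
    return float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0
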