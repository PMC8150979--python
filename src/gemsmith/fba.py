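"""Flux balance analysis: LP core, medium application and knockouts.

FBA solves ``max/min c·v`` subject to steady state ``S·v = 0`` and bounds
``lb <= v <= ub`` with scipy's HiGHS backend.  Exchange fluxes follow the
export-positive convention: uptake of a nutrient is a negative exchange
flux, so a medium specification of maximum uptake rates is applied as lower
bounds ``-rate``; exchanges absent from the medium have uptake closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, build_matrix

__all__ = [
    "FluxDistribution",
    "solve_fba",
    "apply_medium",
    "knockout",
    "FLUX_ZERO_TOL",
]

#: Fluxes below this magnitude are LP solver noise and reported as 0.
FLUX_ZERO_TOL = 1e-6


@dataclass
class FluxDistribution:
    """Optimal flux vector with objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def apply_medium(
    model: MetabolicModel, medium: dict[str, float]
) -> MetabolicModel:
    """Return a copy with exchange lower bounds set from uptake limits.

    ``medium`` maps exchange-reaction id to a maximum uptake rate
    (mmol/gDW/h, >= 0).  Every exchange not named in the medium has uptake
    closed (lower bound 0); export stays open.
    """
    out = model.copy()
    for rid, rate in medium.items():
        if rid not in model.reactions:
            raise KeyError(f"medium names unknown reaction {rid!r}")
        if not model.reactions[rid].is_exchange:
            raise ValueError(f"medium entry {rid!r} is not an exchange reaction")
        if rate < 0:
            raise ValueError(f"negative uptake rate for {rid!r}")
    for rid in model.exchanges:
        rxn = model.reactions[rid]
        if rid in medium:
            out.reactions[rid] = rxn.with_bounds(-float(medium[rid]), rxn.upper_bound)
        else:
            out.reactions[rid] = rxn.with_bounds(max(rxn.lower_bound, 0.0), rxn.upper_bound)
    return out


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str = "max",
    medium: dict[str, float] | None = None,
) -> FluxDistribution:
    """Optimize flux through ``objective`` at steady state.

    Deterministic for a fixed model ordering (HiGHS is deterministic on a
    fixed problem).  Fluxes with magnitude below :data:`FLUX_ZERO_TOL` are
    reported as exactly 0.
    """
    objective = objective or model.objective_reaction_id
    if objective is None or objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if medium is not None:
        model = apply_medium(model, medium)

    sm = build_matrix(model)
    n = len(sm.reaction_ids)
    c = np.zeros(n)
    c[sm.reaction_ids.index(objective)] = -1.0 if sense == "max" else 1.0
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in sm.reaction_ids
    ]
    res = linprog(
        c,
        A_eq=sm.matrix,
        b_eq=np.zeros(len(sm.metabolite_ids)),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FluxDistribution({}, None, "infeasible")
    if res.status == 3:
        return FluxDistribution({}, None, "unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    v = np.asarray(res.x)
    v[np.abs(v) < FLUX_ZERO_TOL] = 0.0
    obj = float(v[sm.reaction_ids.index(objective)])
    return FluxDistribution(dict(zip(sm.reaction_ids, v.tolist())), obj, "optimal")


def knockout(model: MetabolicModel, reaction_ids: list[str] | set[str]) -> MetabolicModel:
    """Copy of ``model`` with both bounds of each named reaction set to 0."""
    out = model.copy()
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
        out.reactions[rid] = model.reactions[rid].with_bounds(0.0, 0.0)
    return out
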