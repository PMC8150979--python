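"""Independent reference implementations used only to check results.

These deliberately avoid the library's solver path: the FBA oracle
enumerates basic feasible points by fixing variables at their bounds and
solving the remaining equality system by least squares, which is exact for
networks of up to ~8 reactions.
"""

import itertools

import numpy as np

from gemsmith.model_core import MetabolicModel, build_matrix


def brute_force_fba(
    model: MetabolicModel, objective: str, tol: float = 1e-8
) -> float | None:
    """Maximum objective flux by vertex enumeration; None if infeasible.

    Every vertex of the flux polytope {S v = 0, lb <= v <= ub} has at
    least n - rank(S) coordinates at a bound; enumerate those supports,
    solve for the free coordinates, and keep feasible points.
    """
    sm = build_matrix(model)
    S = sm.matrix.toarray()
    ids = sm.reaction_ids
    n = len(ids)
    lb = np.array([model.reactions[r].lower_bound for r in ids])
    ub = np.array([model.reactions[r].upper_bound for r in ids])
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    obj_idx = ids.index(objective)

    best = None
    for fixed in itertools.combinations(range(n), k):
        free = [i for i in range(n) if i not in fixed]
        choices = [(lb[i], ub[i]) for i in fixed]
        for vals in itertools.product(*choices):
            v = np.zeros(n)
            v[list(fixed)] = vals
            if free:
                rhs = -S[:, list(fixed)] @ np.asarray(vals)
                sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(v[obj_idx])
            if best is None or val > best:
                best = val
    return best


def exhaustive_gap_fill_size(
    draft: MetabolicModel,
    template: MetabolicModel,
    candidates: list[str],
    objective: str,
    medium: dict[str, float],
    epsilon: float = 1e-3,
) -> int | None:
    """Smallest candidate-subset cardinality restoring growth (None if none)."""
    from gemsmith.fba import solve_fba
    from gemsmith.reconstruction import add_reactions_from

    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            trial = add_reactions_from(draft, template, combo)
            sol = solve_fba(trial, objective, medium=medium)
            if sol.optimal and sol.objective_value >= epsilon - 1e-9:
                return size
    return None


def rebuild_deletion_ratio(
    model: MetabolicModel, gene: str, medium: dict[str, float]
) -> tuple[float, str]:
    """Mutant/wild-type growth ratio by rebuilding the model from scratch,
    dropping every reaction whose GPR is false without ``gene``."""
    from gemsmith.fba import solve_fba

    wt = solve_fba(model, medium=medium)
    assert wt.optimal and wt.objective_value > 0
    keep = {
        rid: rxn
        for rid, rxn in model.reactions.items()
        if rxn.gpr is None or rxn.gpr.evaluate(frozenset({gene}))
    }
    mutant = MetabolicModel(
        id=f"{model.id}_d{gene}",
        metabolites=dict(model.metabolites),
        reactions=keep,
        objective_reaction_id=model.objective_reaction_id,
        compartments=dict(model.compartments),
    )
    sol = solve_fba(mutant, medium=medium)
    if not sol.optimal:
        return 0.0, "infeasible"
    return sol.objective_value / wt.objective_value, "optimal"
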