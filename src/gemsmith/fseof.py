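"""Flux scanning with enforced objective function (FSEOF).

Product flux is enforced at a ladder of values between its level at maximum
biomass and a fraction of its theoretical maximum, maximizing biomass at
each rung.  Reactions whose flux rises with the enforced product flux
(positive least-squares slope, sign-consistent) are overexpression
candidates; their associated genes are the engineering targets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fba import solve_fba
from .model_core import MetabolicModel

__all__ = ["FseofSettings", "FseofTarget", "fseof_scan", "shared_targets"]


@dataclass(frozen=True)
class FseofSettings:
    n_steps: int = 10
    max_fraction: float = 0.9  # of the theoretical product maximum
    min_slope: float = 1e-6
    sign_consistent: bool = True

    def __post_init__(self):
        if not (0 < self.max_fraction <= 1):
            raise ValueError("max_fraction must lie in (0, 1]")
        if self.n_steps < 3:
            raise ValueError("need at least 3 scanning steps")


@dataclass
class FseofTarget:
    reaction_id: str
    trajectory: list[float]  # flux at each feasible enforced step
    slope: float  # least-squares, flux vs enforced product flux
    classification: str  # overexpression | downregulation | unchanged
    genes: frozenset[str] = field(default_factory=frozenset)


def fseof_scan(
    model: MetabolicModel,
    biomass: str,
    product: str,
    settings: FseofSettings = FseofSettings(),
    medium: dict[str, float] | None = None,
) -> list[FseofTarget]:
    """Scan all fluxes while ramping enforced product flux.

    Enforcement fixes both bounds of the product exchange (equality), and
    biomass is maximized at each of ``n_steps`` evenly spaced product-flux
    values from the level at maximum biomass up to ``max_fraction`` of the
    theoretical maximum.  Infeasible steps are dropped with a warning; the
    maximum attainable biomass is checked to be non-increasing along the
    ladder.
    """
    from .fba import apply_medium

    work = apply_medium(model, medium) if medium is not None else model

    vmax_sol = solve_fba(work, product)
    if not vmax_sol.optimal or vmax_sol.objective_value <= 0:
        raise ValueError(f"product {product!r} cannot carry positive flux")
    v_max = vmax_sol.objective_value

    base_sol = solve_fba(work, biomass)
    if not base_sol.optimal:
        raise RuntimeError("model infeasible under the given medium")
    v_0 = base_sol.fluxes.get(product, 0.0)

    enforced = np.linspace(v_0, settings.max_fraction * v_max, settings.n_steps)
    rxn_ids = list(work.reactions)
    levels: list[float] = []
    flux_rows: list[dict[str, float]] = []
    biomass_track: list[float] = []
    for level in enforced:
        step = work.copy()
        step.reactions[product] = work.reactions[product].with_bounds(level, level)
        sol = solve_fba(step, biomass)
        if not sol.optimal:
            warnings.warn(f"enforced product flux {level:.4g} infeasible; step dropped")
            continue
        assert abs(sol.fluxes[product] - level) <= 1e-6
        levels.append(float(level))
        flux_rows.append(sol.fluxes)
        biomass_track.append(sol.objective_value)
    if len(levels) < 3:
        raise RuntimeError("fewer than 3 feasible enforcement steps")
    if any(b2 > b1 + 1e-6 for b1, b2 in zip(biomass_track, biomass_track[1:])):
        raise AssertionError("maximum biomass increased along the product ladder")

    x = np.asarray(levels)
    x_c = x - x.mean()
    denom = float(x_c @ x_c)
    targets: list[FseofTarget] = []
    for rid in rxn_ids:
        y = np.array([row.get(rid, 0.0) for row in flux_rows])
        slope = float(x_c @ (y - y.mean())) / denom if denom > 0 else 0.0
        cls = _classify(y, slope, settings)
        targets.append(
            FseofTarget(
                reaction_id=rid,
                trajectory=y.tolist(),
                slope=slope,
                classification=cls,
                genes=work.reactions[rid].genes,
            )
        )
    return targets


def _classify(y: np.ndarray, slope: float, settings: FseofSettings) -> str:
    nonzero = y[np.abs(y) > 0]
    if settings.sign_consistent and nonzero.size and (
        np.any(nonzero > 0) and np.any(nonzero < 0)
    ):
        return "unchanged"  # sign flips point to alternate-optima noise
    if slope > settings.min_slope and nonzero.size:
        return "overexpression"
    if slope < -settings.min_slope:
        return "downregulation"
    return "unchanged"


def shared_targets(
    results: dict[str, list[FseofTarget]],
) -> tuple[dict[int, list[tuple[str, frozenset[str]]]], list[str]]:
    """Intersect overexpression targets across products.

    Returns ``(by_count, full_intersection)``: ``by_count[k]`` lists
    ``(reaction id, genes)`` classified overexpression in exactly ``k``
    products; the full intersection (reactions shared by all products) is
    reported separately.
    """
    if len(results) < 2:
        raise ValueError("need at least two products to intersect")
    sets = {
        prod: {t.reaction_id: t.genes for t in targets if t.classification == "overexpression"}
        for prod, targets in results.items()
    }
    counts: dict[str, int] = {}
    genes: dict[str, frozenset[str]] = {}
    for prod, tset in sets.items():
        for rid, g in tset.items():
            counts[rid] = counts.get(rid, 0) + 1
            genes[rid] = g
    by_count: dict[int, list[tuple[str, frozenset[str]]]] = {}
    for rid, k in sorted(counts.items()):
        by_count.setdefault(k, []).append((rid, genes[rid]))
    full = sorted(rid for rid, k in counts.items() if k == len(results))
    return by_count, full
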