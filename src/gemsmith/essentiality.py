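"""Single-gene deletion, essentiality classification and paralogue metrics.

A gene knockout disables every reaction whose GPR evaluates FALSE with that
gene removed; the mutant's optimal growth is compared to the wild type.  A
gene is essential when the knockout reduces growth by two-thirds or more
(growth ratio <= 1/3, inclusive) or renders the problem infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fba import knockout, solve_fba
from .gpr import Gpr
from .model_core import MetabolicModel

__all__ = [
    "DeletionResult",
    "EssentialityReport",
    "ParalogueComparisonRow",
    "eval_gpr",
    "single_gene_deletion",
    "classify_essential",
    "paralogue_fraction",
    "cross_model_comparison",
    "DEFAULT_ESSENTIALITY_RATIO",
]

#: Growth ratio at or below which a knockout counts as essential
#: (a reduction by two-thirds or more).
DEFAULT_ESSENTIALITY_RATIO = 1.0 / 3.0


def eval_gpr(expr: Gpr | None, deleted: set[str] | frozenset[str]) -> bool:
    """Truth of a GPR with ``deleted`` genes FALSE; no GPR is always active."""
    if expr is None:
        return True
    return expr.evaluate(frozenset(deleted))


@dataclass(frozen=True)
class DeletionResult:
    gene: str
    growth_ratio: float  # mutant/wild-type objective; 0 when infeasible
    status: str  # optimal | infeasible


@dataclass
class EssentialityReport:
    results: list[DeletionResult]
    threshold_ratio: float = DEFAULT_ESSENTIALITY_RATIO

    @property
    def essential_genes(self) -> frozenset[str]:
        return frozenset(
            r.gene
            for r in self.results
            if r.status != "optimal" or r.growth_ratio <= self.threshold_ratio + 1e-6
        )


def single_gene_deletion(
    model: MetabolicModel,
    medium: dict[str, float] | None = None,
    genes: list[str] | None = None,
) -> list[DeletionResult]:
    """Knock out each gene in turn and record the mutant/wild-type ratio.

    The wild type is solved once; per gene only the reactions whose GPR
    goes inactive are constrained to zero flux.
    """
    wt = solve_fba(model, medium=medium)
    if not wt.optimal or wt.objective_value <= 0:
        raise RuntimeError("wild-type model does not grow; essentiality undefined")
    gene_list = sorted(genes if genes is not None else model.genes)

    # index: gene -> reactions whose GPR mentions it
    touches: dict[str, list[str]] = {g: [] for g in gene_list}
    for rxn in model.reactions.values():
        for g in rxn.genes:
            if g in touches:
                touches[g].append(rxn.id)

    results: list[DeletionResult] = []
    for gene in gene_list:
        dead = [
            rid
            for rid in touches[gene]
            if not eval_gpr(model.reactions[rid].gpr, {gene})
        ]
        if not dead:
            results.append(DeletionResult(gene, 1.0, "optimal"))
            continue
        sol = solve_fba(knockout(model, dead), medium=medium)
        if not sol.optimal:
            results.append(DeletionResult(gene, 0.0, "infeasible"))
        else:
            ratio = sol.objective_value / wt.objective_value
            results.append(DeletionResult(gene, ratio, "optimal"))
    return results


def classify_essential(
    results: list[DeletionResult],
    threshold_ratio: float = DEFAULT_ESSENTIALITY_RATIO,
) -> EssentialityReport:
    return EssentialityReport(results=list(results), threshold_ratio=threshold_ratio)


def paralogue_fraction(model: MetabolicModel, max_terms: int = 1024) -> float:
    """Fraction of gene-associated reactions whose GPR offers >= 2
    alternative gene sets (isozymes or alternative complexes)."""
    with_gpr = [r for r in model.reactions.values() if r.gpr is not None]
    if not with_gpr:
        return 0.0
    n_paralogued = sum(1 for r in with_gpr if r.gpr.has_alternatives(max_terms))
    return n_paralogued / len(with_gpr)


@dataclass(frozen=True)
class ParalogueComparisonRow:
    reaction_a: str
    essential_genes_a: frozenset[str]
    reaction_b: str
    paralogue_genes_b: frozenset[str]


def cross_model_comparison(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    reaction_map: dict[str, str],
    essentials_a: frozenset[str] | set[str],
) -> tuple[list[ParalogueComparisonRow], int]:
    """Reactions gated by a paralogue-free essential gene in A whose mapped
    counterpart in B offers >= 2 alternative gene sets.

    Returns the rows plus the count of model-A reactions (with essential
    genes, no alternatives) that had no counterpart in the map.
    """
    rows: list[ParalogueComparisonRow] = []
    unmapped = 0
    for rxn in model_a.reactions.values():
        if rxn.gpr is None:
            continue
        ess = rxn.genes & frozenset(essentials_a)
        if not ess or rxn.gpr.has_alternatives():
            continue
        if rxn.id not in reaction_map:
            unmapped += 1
            continue
        rid_b = reaction_map[rxn.id]
        rxn_b = model_b.reactions.get(rid_b)
        if rxn_b is None or rxn_b.gpr is None:
            continue
        if rxn_b.gpr.has_alternatives():
            rows.append(
                ParalogueComparisonRow(
                    reaction_a=rxn.id,
                    essential_genes_a=frozenset(ess),
                    reaction_b=rid_b,
                    paralogue_genes_b=rxn_b.genes,
                )
            )
    return rows, unmapped
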