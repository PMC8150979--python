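"""Core domain types for genome-scale metabolic models.

A :class:`MetabolicModel` holds metabolites, reactions (with flux bounds and
GPR rules), an objective reaction and compartments; the stoichiometric matrix
``S`` is derived from it on demand.  Flux units are mmol/gDW/h throughout
(the biomass pseudo-reaction flux is in 1/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .gpr import Gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "ValidationIssue",
    "validate_model",
    "prune_disconnected",
    "build_matrix",
    "REACTION_KINDS",
    "DEFAULT_LB",
    "DEFAULT_UB",
]

#: Community-convention big-M flux cap for unspecified bounds.
DEFAULT_LB = -1000.0
DEFAULT_UB = 1000.0

REACTION_KINDS = ("enzymatic", "spontaneous", "transport", "exchange", "pseudo")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    annotations: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = DEFAULT_LB
    upper_bound: float = DEFAULT_UB
    gpr: Gpr | None = None
    subsystem: str = ""
    kind: str = "enzymatic"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_reaction_id: str | None = None
    compartments: dict[str, str] = field(default_factory=dict)
    declared_genes: frozenset[str] | None = None

    @property
    def genes(self) -> frozenset[str]:
        derived: set[str] = set()
        for r in self.reactions.values():
            derived |= r.genes
        if self.declared_genes:
            derived |= self.declared_genes
        return frozenset(derived)

    @property
    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            objective_reaction_id=self.objective_reaction_id,
            compartments=dict(self.compartments),
            declared_genes=self.declared_genes,
        )

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def summary(self) -> dict[str, int]:
        return {
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "genes": len(self.genes),
        }


@dataclass(frozen=True)
class ValidationIssue:
    entity: str
    rule: str
    detail: str = ""


def validate_model(model: MetabolicModel) -> list[ValidationIssue]:
    """Check structural invariants; issues are data, not exceptions."""
    issues: list[ValidationIssue] = []
    compartments = set(model.compartments) if model.compartments else None
    for met in model.metabolites.values():
        if compartments is not None and met.compartment not in compartments:
            issues.append(
                ValidationIssue(met.id, "unknown-compartment", met.compartment)
            )
    for rxn in model.reactions.values():
        if rxn.lower_bound > rxn.upper_bound:
            issues.append(
                ValidationIssue(
                    rxn.id,
                    "inverted-bounds",
                    f"lb={rxn.lower_bound} > ub={rxn.upper_bound}",
                )
            )
        if not rxn.stoichiometry:
            issues.append(ValidationIssue(rxn.id, "empty-stoichiometry"))
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in model.metabolites:
                issues.append(
                    ValidationIssue(rxn.id, "dangling-metabolite", met_id)
                )
            if coeff == 0:
                issues.append(ValidationIssue(rxn.id, "zero-coefficient", met_id))
        if rxn.kind not in REACTION_KINDS:
            issues.append(ValidationIssue(rxn.id, "unknown-kind", rxn.kind))
        if rxn.kind == "exchange" and len(rxn.stoichiometry) != 1:
            issues.append(ValidationIssue(rxn.id, "multi-metabolite-exchange"))
    if (
        model.objective_reaction_id is not None
        and model.objective_reaction_id not in model.reactions
    ):
        issues.append(
            ValidationIssue(
                model.objective_reaction_id, "missing-objective-reaction"
            )
        )
    if model.declared_genes is not None:
        derived = frozenset().union(*(r.genes for r in model.reactions.values())) \
            if model.reactions else frozenset()
        for g in derived - model.declared_genes:
            issues.append(ValidationIssue(g, "undeclared-gene"))
    return issues


def prune_disconnected(
    model: MetabolicModel,
) -> tuple[MetabolicModel, list[str]]:
    """Iteratively remove dead-end reactions until fixpoint.

    A metabolite participating in exactly one reaction is a dead end: at
    steady state that reaction can never carry flux, so it is disconnected
    from the functioning network.  Removal is iterated because pruning one
    reaction can orphan the next (a dangling appendix chain unravels from
    its tip).  Exchange and pseudo reactions are boundary/sink constructs
    and are never removed; the feasible flux space is preserved exactly.
    """
    rxns = dict(model.reactions)
    removed: list[str] = []
    while True:
        usage: dict[str, int] = {}
        for r in rxns.values():
            for m in r.stoichiometry:
                usage[m] = usage.get(m, 0) + 1
        orphans = [
            r.id
            for r in rxns.values()
            if r.kind not in ("exchange", "pseudo")
            and any(usage[m] == 1 for m in r.stoichiometry)
        ]
        if not orphans:
            break
        for rid in orphans:
            if rid == model.objective_reaction_id:
                raise ValueError(
                    f"pruning would remove the objective reaction {rid!r}"
                )
            del rxns[rid]
            removed.append(rid)
    kept_mets = {m for r in rxns.values() for m in r.stoichiometry}
    out = model.copy()
    out.reactions = rxns
    out.metabolites = {
        k: v for k, v in model.metabolites.items() if k in kept_mets
    }
    return out, removed


@dataclass
class StoichiometricMatrix:
    """Sparse S with explicit row (metabolite) and column (reaction) order."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    matrix: sparse.csc_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    row = {m: i for i, m in enumerate(met_ids)}
    data, rows, cols = [], [], []
    for j, rid in enumerate(rxn_ids):
        for m, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(row[m])
            cols.append(j)
            data.append(coeff)
    mat = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return StoichiometricMatrix(met_ids, rxn_ids, mat)
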