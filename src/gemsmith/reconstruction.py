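"""Template-based draft reconstruction.

The pipeline mirrors the standard homology-transfer workflow for building a
genome-scale model of a new organism from a curated template of a related
species:

1. filter a bidirectional protein-homology search with E-value / alignment
   length / identity cutoffs to get an ortholog map;
2. transfer template reactions whose GPR can be rewritten in target genes;
3. transfer gene-less reactions (exchanges, transport, spontaneous, biomass
   pseudo-reactions) and prune dead ends;
4. gap-fill: add a minimum-cardinality set of template reactions so the
   biomass objective can carry flux (MILP with binary use-indicators);
5. merge externally sourced gene-reaction records not already covered;
6. assign reaction reversibility from standard-condition Gibbs free
   energies with a +/-30 kJ/mol threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import apply_medium, solve_fba
from .gpr import Gpr
from .model_core import (
    DEFAULT_LB,
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
    prune_disconnected,
)

__all__ = [
    "HomologyHit",
    "FilterCutoffs",
    "OrthologMap",
    "DeltaGRecord",
    "read_hit_table",
    "read_dg_table",
    "filter_orthologs",
    "draft_from_template",
    "transfer_nongene_reactions",
    "gap_fill",
    "gap_fill_substrates",
    "merge_external_reactions",
    "assign_reversibility",
    "add_reactions_from",
    "genomic_coverage",
    "UnfillableError",
]


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    e_value: float
    identity: float
    alignment_length: int


@dataclass(frozen=True)
class FilterCutoffs:
    """Inclusive cutoffs on protein-homology hits."""

    max_evalue: float = 1e-50
    min_alignment_length: int = 90
    min_identity: float = 40.0

    def passes(self, hit: HomologyHit) -> bool:
        return (
            hit.e_value <= self.max_evalue
            and hit.alignment_length >= self.min_alignment_length
            and hit.identity >= self.min_identity
        )


@dataclass
class OrthologMap:
    """Bidirectionally supported (target gene, template gene) pairs."""

    pairs: frozenset[tuple[str, str]]

    def targets_of(self, template_gene: str) -> list[str]:
        return sorted(t for t, s in self.pairs if s == template_gene)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


#: Column names of the 12-column tabular alignment format.
_HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Parse a 12-column tab-separated alignment table."""
    hits: list[HomologyHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(
                HomologyHit(
                    query=fields[0],
                    subject=fields[1],
                    identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    e_value=float(fields[10]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable row: {exc}") from exc
    return hits


def filter_orthologs(
    forward_hits: Iterable[HomologyHit],
    reverse_hits: Iterable[HomologyHit],
    cutoffs: FilterCutoffs = FilterCutoffs(),
) -> OrthologMap:
    """Keep (target, template) pairs with a passing hit in *both* directions.

    ``forward_hits`` are target-vs-template (query = target gene); reverse
    hits are template-vs-target.  A pair survives iff some forward hit and
    some reverse hit between the same two genes each pass all cutoffs.
    """
    fwd = {
        (h.query, h.subject) for h in forward_hits if cutoffs.passes(h)
    }
    rev = {
        (h.subject, h.query) for h in reverse_hits if cutoffs.passes(h)
    }
    return OrthologMap(frozenset(fwd & rev))


# ---------------------------------------------------------------------------
# reaction transfer
# ---------------------------------------------------------------------------

def draft_from_template(
    template: MetabolicModel,
    orthologs: OrthologMap,
    keep_all_orthologs: bool = True,
) -> MetabolicModel:
    """Transfer template reactions whose GPR survives ortholog rewriting.

    Every template gene in a GPR is substituted by the OR of its target
    orthologs (all passing orthologs by default, preserving isozyme
    structure); genes without orthologs become FALSE.  Reactions whose
    rewritten GPR is unsatisfiable are excluded.  Gene-less reactions are
    not transferred here (see :func:`transfer_nongene_reactions`).
    """
    mapping: dict[str, Gpr | None] = {}
    for gene in template.genes:
        targets = orthologs.targets_of(gene)
        if not keep_all_orthologs and targets:
            targets = targets[:1]
        if targets:
            mapping[gene] = Gpr.or_([Gpr.leaf(t) for t in targets])
        else:
            mapping[gene] = None

    reactions: dict[str, Reaction] = {}
    for rxn in template.reactions.values():
        if rxn.gpr is None:
            continue
        new_gpr = rxn.gpr.substitute(mapping)
        if new_gpr is None:
            continue
        reactions[rxn.id] = Reaction(
            id=rxn.id,
            name=rxn.name,
            stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
            gpr=new_gpr,
            subsystem=rxn.subsystem,
            kind=rxn.kind,
        )
    used = {m for r in reactions.values() for m in r.stoichiometry}
    return MetabolicModel(
        id=f"{template.id}_draft",
        metabolites={k: v for k, v in template.metabolites.items() if k in used},
        reactions=reactions,
        objective_reaction_id=None,
        compartments=dict(template.compartments),
    )


def transfer_nongene_reactions(
    template: MetabolicModel, draft: MetabolicModel
) -> MetabolicModel:
    """Add the template's gene-less reactions to the draft, then prune.

    Exchanges, transport and spontaneous reactions, and pseudo-reactions
    (biomass and its macromolecule drains) carry no GPR and are copied
    verbatim unless already present.  The template's objective reaction id
    is adopted when it comes across.  Dead-end pruning follows.
    """
    out = draft.copy()
    for rxn in template.reactions.values():
        if rxn.gpr is not None:
            continue
        if rxn.id in out.reactions:
            if out.reactions[rxn.id].stoichiometry != rxn.stoichiometry:
                raise ValueError(
                    f"reaction id {rxn.id!r} exists with different stoichiometry"
                )
            continue
        out.reactions[rxn.id] = rxn
        for m in rxn.stoichiometry:
            if m not in out.metabolites:
                out.metabolites[m] = template.metabolites[m]
    if (
        out.objective_reaction_id is None
        and template.objective_reaction_id in out.reactions
    ):
        out.objective_reaction_id = template.objective_reaction_id
    pruned, _ = prune_disconnected(out)
    return pruned


# ---------------------------------------------------------------------------
# gap-filling
# ---------------------------------------------------------------------------

class UnfillableError(RuntimeError):
    """No candidate subset restores growth."""

    def __init__(self, blocked: list[str]):
        self.blocked_precursors = blocked
        detail = ", ".join(blocked) if blocked else "unknown"
        super().__init__(f"gap-filling failed; blocked biomass precursors: {detail}")


def add_reactions_from(
    base: MetabolicModel, template: MetabolicModel, extra: Iterable[str]
) -> MetabolicModel:
    out = base.copy()
    for rid in extra:
        rxn = template.reactions[rid]
        out.reactions[rid] = rxn
        for m in rxn.stoichiometry:
            if m not in out.metabolites:
                out.metabolites[m] = template.metabolites[m]
    return out


def _grows(
    model: MetabolicModel, objective: str, medium: dict[str, float], epsilon: float
) -> bool:
    sol = solve_fba(model, objective, medium=medium)
    return sol.optimal and sol.objective_value >= epsilon - 1e-9


def gap_fill(
    draft: MetabolicModel,
    template: MetabolicModel,
    objective: str,
    medium: dict[str, float],
    epsilon: float = 1e-3,
    big_m: float = 1000.0,
) -> list[str]:
    """Minimum-cardinality template-reaction set restoring growth.

    Formulated as a MILP over the draft plus all candidate reactions
    (template reactions absent from the draft): binary use-indicators
    ``y_j`` with ``|v_j| <= M y_j``, steady state, objective flux
    ``>= epsilon``; minimize ``sum(y)``.  Ties at the optimal cardinality
    are broken lexicographically by reaction-id tuple (by enumerating
    size-k subsets when that is tractable).  Returns ``[]`` when the draft
    already grows.
    """
    if objective not in draft.reactions:
        raise KeyError(f"objective reaction {objective!r} not in draft")
    if _grows(draft, objective, medium, epsilon):
        return []

    candidates = sorted(set(template.reactions) - set(draft.reactions))
    full = add_reactions_from(draft, template, candidates)
    if not _grows(full, objective, medium, epsilon):
        raise UnfillableError(_blocked_precursors(full, objective, medium))

    chosen = _gap_fill_milp(
        draft, template, candidates, objective, medium, epsilon, big_m
    )
    if chosen is None:
        # greedy fallback (flagged non-minimal by ordering semantics)
        chosen = _gap_fill_greedy(draft, template, candidates, objective, medium, epsilon)
    k = len(chosen)

    # lexicographic tie-break: first feasible size-k subset in id order
    if k > 0 and math.comb(len(candidates), k) <= 2000:
        for combo in itertools.combinations(candidates, k):
            if _grows(add_reactions_from(draft, template, combo), objective, medium, epsilon):
                return list(combo)
    return sorted(chosen)


def _gap_fill_milp(
    draft: MetabolicModel,
    template: MetabolicModel,
    candidates: list[str],
    objective: str,
    medium: dict[str, float],
    epsilon: float,
    big_m: float,
) -> list[str] | None:
    from .model_core import build_matrix

    model = apply_medium(add_reactions_from(draft, template, candidates), medium)
    sm = build_matrix(model)
    rxn_index = {r: j for j, r in enumerate(sm.reaction_ids)}
    n = len(sm.reaction_ids)
    m_cand = len(candidates)

    # variables: v (n) then y (m_cand)
    c = np.concatenate([np.zeros(n), np.ones(m_cand)])
    integrality = np.concatenate([np.zeros(n), np.ones(m_cand)])

    lb = np.array([model.reactions[r].lower_bound for r in sm.reaction_ids])
    ub = np.array([model.reactions[r].upper_bound for r in sm.reaction_ids])
    lb = np.clip(lb, -big_m, big_m)
    ub = np.clip(ub, -big_m, big_m)
    var_lb = np.concatenate([lb, np.zeros(m_cand)])
    var_ub = np.concatenate([ub, np.ones(m_cand)])
    # enforce the growth requirement directly on the objective variable
    j_obj = rxn_index[objective]
    var_lb[j_obj] = max(var_lb[j_obj], epsilon)

    constraints = [
        LinearConstraint(
            sparse.hstack([sm.matrix, sparse.csr_matrix((len(sm.metabolite_ids), m_cand))]),
            0.0,
            0.0,
        )
    ]
    # v_j - M y_j <= 0 and -v_j - M y_j <= 0
    rows, cols, data = [], [], []
    for i, rid in enumerate(candidates):
        j = rxn_index[rid]
        rows += [2 * i, 2 * i, 2 * i + 1, 2 * i + 1]
        cols += [j, n + i, j, n + i]
        data += [1.0, -big_m, -1.0, -big_m]
    ind = sparse.csr_matrix((data, (rows, cols)), shape=(2 * m_cand, n + m_cand))
    constraints.append(LinearConstraint(ind, -np.inf, 0.0))

    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"time_limit": 300},
    )
    if res.status != 0 or res.x is None:
        return None
    y = res.x[n:]
    return [candidates[i] for i in range(m_cand) if y[i] > 0.5]


def _gap_fill_greedy(
    draft, template, candidates, objective, medium, epsilon
) -> list[str]:
    chosen = list(candidates)
    for rid in sorted(candidates, reverse=True):
        trial = [r for r in chosen if r != rid]
        if _grows(add_reactions_from(draft, template, trial), objective, medium, epsilon):
            chosen = trial
    return chosen


def _blocked_precursors(
    model: MetabolicModel, objective: str, medium: dict[str, float]
) -> list[str]:
    """Biomass substrates that cannot be produced even with all candidates."""
    blocked = []
    obj_rxn = model.reactions[objective]
    for met, coeff in obj_rxn.stoichiometry.items():
        if coeff >= 0:
            continue
        probe = model.copy()
        probe.reactions["_sink_probe"] = Reaction(
            id="_sink_probe", stoichiometry={met: -1.0}, lower_bound=0.0,
            upper_bound=DEFAULT_UB, kind="pseudo",
        )
        sol = solve_fba(probe, "_sink_probe", medium=medium)
        if not sol.optimal or sol.objective_value < 1e-6:
            blocked.append(met)
    return blocked


def gap_fill_substrates(
    model: MetabolicModel,
    template: MetabolicModel,
    substrates: Sequence[str],
    base_medium: dict[str, float],
    carbon_exchange: str,
    objective: str | None = None,
    epsilon: float = 1e-3,
    uptake: float = 1.0,
) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """Gap-fill growth on each substrate as the sole carbon source.

    ``base_medium`` is the minimal medium; ``carbon_exchange`` names its
    carbon-source exchange, which is swapped for each substrate exchange in
    turn.  After each fill, added reactions carrying zero flux in the
    verifying optimal solution are removed again.  Returns the final model
    and the per-substrate additions that survived.
    """
    objective = objective or model.objective_reaction_id
    out = model.copy()
    added: dict[str, list[str]] = {}
    for sub in substrates:
        medium = {k: v for k, v in base_medium.items() if k != carbon_exchange}
        medium[sub] = uptake
        if sub not in out.reactions:
            if sub not in template.reactions:
                raise KeyError(f"substrate exchange {sub!r} in neither model")
            out = add_reactions_from(out, template, [sub])
        fills = gap_fill(out, template, objective, medium, epsilon)
        out = add_reactions_from(out, template, fills)
        sol = solve_fba(out, objective, medium=medium)
        kept = [r for r in fills if sol.optimal and abs(sol.fluxes.get(r, 0.0)) > 0]
        for r in set(fills) - set(kept):
            del out.reactions[r]
        added[sub] = kept
        final = solve_fba(out, objective, medium=medium)
        if not final.optimal or final.objective_value < epsilon - 1e-9:
            raise UnfillableError([sub])
    return out, added


# ---------------------------------------------------------------------------
# external additions and reversibility
# ---------------------------------------------------------------------------

def merge_external_reactions(
    draft: MetabolicModel,
    additions: Iterable[Reaction],
    metabolites: dict[str, Metabolite] | None = None,
) -> tuple[MetabolicModel, list[str]]:
    """Add externally sourced gene-reaction records not already covered.

    A record is added iff none of its genes already occur in the draft and
    its reaction id is new.  A record duplicating an existing id with
    identical stoichiometry is skipped; a stoichiometry conflict raises.
    Returns the merged model and the skipped record ids.
    """
    out = draft.copy()
    skipped: list[str] = []
    known_genes = set(draft.genes)
    for rxn in additions:
        if rxn.id in out.reactions:
            if out.reactions[rxn.id].stoichiometry != rxn.stoichiometry:
                raise ValueError(
                    f"addition {rxn.id!r} conflicts with existing stoichiometry"
                )
            skipped.append(rxn.id)
            continue
        if rxn.genes & known_genes:
            skipped.append(rxn.id)
            continue
        out.reactions[rxn.id] = rxn
        for m in rxn.stoichiometry:
            if m not in out.metabolites:
                if metabolites and m in metabolites:
                    out.metabolites[m] = metabolites[m]
                else:
                    out.metabolites[m] = Metabolite(id=m, compartment=_guess_compartment(m))
    return out, skipped


def _guess_compartment(met_id: str) -> str:
    return met_id.rsplit("_", 1)[-1] if "_" in met_id else "c"


def genomic_coverage(n_model_genes: int, n_genome_genes: int) -> float:
    """Percentage of genome-annotated genes captured by the model, rounded
    to one decimal (the conventional headline figure for a reconstruction)."""
    if n_genome_genes <= 0:
        raise ValueError("genome gene count must be positive")
    if not (0 <= n_model_genes <= n_genome_genes):
        raise ValueError("model gene count must lie in [0, genome gene count]")
    return round(100.0 * n_model_genes / n_genome_genes, 1)


@dataclass(frozen=True)
class DeltaGRecord:
    """Standard-condition Gibbs free energy of a reaction (kJ/mol)."""

    reaction_id: str
    delta_g_prime: float | None
    available: bool = True

    def __post_init__(self):
        if not self.available and self.delta_g_prime is not None:
            raise ValueError("unavailable record must carry no value")


def read_dg_table(path: str | Path) -> list[DeltaGRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        avail = bool(row.get("available", True)) and not pd.isna(row["delta_g_prime_kj_mol"])
        records.append(
            DeltaGRecord(
                reaction_id=str(row["reaction_id"]),
                delta_g_prime=float(row["delta_g_prime_kj_mol"]) if avail else None,
                available=avail,
            )
        )
    return records


def assign_reversibility(
    model: MetabolicModel,
    records: Iterable[DeltaGRecord],
    threshold: float = -30.0,
    symmetric: bool = True,
) -> tuple[MetabolicModel, list[str]]:
    """Set reaction bounds from Gibbs free energies.

    ``dG' <= threshold`` (default -30 kJ/mol, inclusive) makes a reaction
    forward-irreversible ``(0, ub)``; with ``symmetric`` on, ``dG' >=
    -threshold`` makes it reverse-irreversible ``(lb, 0)``; in between the
    reaction is reversible with default bounds.  Records without a value
    leave bounds untouched and are returned for manual curation.
    """
    out = model.copy()
    manual: list[str] = []
    for rec in records:
        if rec.reaction_id not in model.reactions:
            raise KeyError(f"delta-G record for unknown reaction {rec.reaction_id!r}")
        rxn = out.reactions[rec.reaction_id]
        if not rec.available:
            manual.append(rec.reaction_id)
            continue
        dg = rec.delta_g_prime
        if dg <= threshold:
            out.reactions[rec.reaction_id] = rxn.with_bounds(0.0, max(rxn.upper_bound, 0.0) or DEFAULT_UB)
        elif symmetric and dg >= -threshold:
            out.reactions[rec.reaction_id] = rxn.with_bounds(min(rxn.lower_bound, 0.0) if rxn.lower_bound < 0 else DEFAULT_LB, 0.0)
        else:
            out.reactions[rec.reaction_id] = rxn.with_bounds(DEFAULT_LB, DEFAULT_UB)
    return out, manual
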