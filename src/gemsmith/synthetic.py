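"""Seeded toy ecosystems exercising every pipeline stage with known truth.

The template network is a miniature prokaryote metabolism: a glycolysis-like
trunk (hexokinase -> lumped lower glycolysis -> pyruvate kinase), a pentose-
phosphate-like branch supplying an erythrose-4-phosphate analogue, a
shikimate-like chain to a chorismate analogue feeding two product pathways,
amino-acid synthesis into a biomass reaction with an ATP (GAEC) term, a
separate maintenance (NGAM) reaction, exchanges, gene-less transport and
spontaneous reactions, and designed isozyme/complex GPR structure.

With glucose-analogue uptake ``q``, maintenance ``m`` and biomass ATP cost
``gaec`` the optimal growth rate has the closed form::

    mu* = min((3 q - m) / (1 + gaec), 2 q)

(three net ATP per glucose; two pyruvate per glucose capping amino-acid
supply), which the test suite uses as an algebraic oracle.

All randomness flows from a single integer seed; regeneration is
bit-reproducible.  Identifiers carry a reserved ``toy_`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_LB,
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .gpr import parse_gpr
from .reconstruction import DeltaGRecord, HomologyHit

__all__ = [
    "ToyConfig",
    "EcosystemTruth",
    "ToyEcosystem",
    "make_template_model",
    "make_ortholog_hits",
    "make_cultivation",
    "make_dg_table",
    "make_ecosystem",
    "toy_medium",
    "write_hit_table",
    "closed_form_growth",
]


@dataclass(frozen=True)
class ToyConfig:
    """Generation parameters; defaults are the study conditions."""

    n_reactions: int = 36           # total template reactions (28-80)
    paralogue_fraction: float = 0.25  # of gene-associated reactions with isozymes
    n_complex_reactions: int = 1     # AND-complexes beyond the designed one
    gaec: float = 2.0                # template biomass ATP cost, mmol/gDW
    dropped_genes: tuple[str, ...] = ("toy_g_aa",)
    degraded_genes: tuple[str, ...] = ("toy_g_pA",)
    # cultivation defaults: yield and growth as measured for the organism,
    # triplicates sampled every 6 h over 72 h
    yield_mmol_per_gdw: float = 24.7
    mu: float = 0.09
    x0: float = 0.02
    g0: float = 60.0
    sigma: float = 0.3
    dt: float = 6.0
    horizon: float = 72.0
    n_replicates: int = 3

    def __post_init__(self):
        if not (28 <= self.n_reactions <= 80):
            # the designed core (trunk, branch, products, exchanges) is 28
            raise ValueError("n_reactions must lie in [28, 80]")
        if not (0 <= self.paralogue_fraction <= 0.7):
            raise ValueError("paralogue_fraction out of range")


def closed_form_growth(q: float, ngam: float, gaec: float) -> float:
    """Analytic optimum of the toy template (see module docstring)."""
    return max(0.0, min((3.0 * q - ngam) / (1.0 + gaec), 2.0 * q))


def toy_medium(glc_uptake: float = 1.0, carbon: str = "EX_toy_glcA") -> dict[str, float]:
    """Minimal medium: carbon source plus free inorganic exchanges."""
    return {
        carbon: glc_uptake,
        "EX_toy_nh4": 1000.0,
        "EX_toy_pi": 1000.0,
        "EX_toy_h2o": 1000.0,
        "EX_toy_h": 1000.0,
    }


# core reactions whose loss breaks biomass formation (each the sole route)
_BIOMASS_SUPPORT = (
    "toy_GLCt", "toy_NH4t", "toy_PYRt", "toy_HEX", "toy_EMP", "toy_PYK",
    "toy_AAS", "EX_toy_glcA", "EX_toy_nh4", "EX_toy_pi", "EX_toy_h2o",
    "EX_toy_h", "EX_toy_pyr", "toy_NGAM", "toy_BIOMASS",
)

#: product-A pathway: every reaction here carries exactly the enforced
#: product flux during a scan (slope 1 by stoichiometry)
_PRODUCT_A_PATH = (
    "toy_PPP", "toy_DAHPS", "toy_SHK1", "toy_SHK2", "toy_PRODA",
    "toy_PRODAt", "EX_toy_prodA",
)

_CORE_ESSENTIAL = {  # sole gatekeepers of biomass-path reactions
    "toy_HEX": "toy_g_hex",
    "toy_EMP": "toy_g_emp",
    "toy_PYK": "toy_g_pyk",
    "toy_AAS": "toy_g_aa",
}


def _met(mid: str, comp: str, name: str = "") -> Metabolite:
    return Metabolite(id=mid, name=name or mid, compartment=comp)


def make_template_model(
    seed: int = 0, config: ToyConfig = ToyConfig()
) -> MetabolicModel:
    """Build the template network; deterministic in ``(seed, config)``."""
    rng = np.random.default_rng(seed)
    mets: dict[str, Metabolite] = {}
    for mid in (
        "toy_glcA_e", "toy_glcA_c", "toy_fruA_e", "toy_fruA_c", "toy_g6p_c",
        "toy_pep_c", "toy_pyr_c", "toy_pyr_e", "toy_e4p_c", "toy_dahp_c",
        "toy_shk_c", "toy_cho_c", "toy_prodA_c", "toy_prodA_e",
        "toy_prodB_c", "toy_prodB_e", "toy_aa_c", "toy_nh4_e", "toy_nh4_c",
        "toy_atp_c", "toy_adp_c", "toy_pi_c", "toy_h2o_c", "toy_h_c",
    ):
        mets[mid] = _met(mid, "e" if mid.endswith("_e") else "c")

    def rxn(rid, stoich, gpr=None, kind="enzymatic", lb=0.0, ub=DEFAULT_UB, sub=""):
        return Reaction(
            id=rid, name=rid, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub,
            gpr=parse_gpr(gpr) if gpr else None, kind=kind, subsystem=sub,
        )

    reactions: dict[str, Reaction] = {}

    def add(r: Reaction):
        reactions[r.id] = r

    for mid in ("glcA", "fruA", "nh4", "pi", "h2o", "h", "pyr", "prodA", "prodB"):
        comp = "c" if mid in ("pi", "h2o", "h") else "e"
        add(rxn(f"EX_toy_{mid}", {f"toy_{mid}_{comp}": -1.0},
                kind="exchange", lb=DEFAULT_LB))
    add(rxn("toy_GLCt", {"toy_glcA_e": -1, "toy_glcA_c": 1}, kind="transport", sub="transport"))
    add(rxn("toy_FRUt", {"toy_fruA_e": -1, "toy_fruA_c": 1}, kind="transport", sub="transport"))
    add(rxn("toy_NH4t", {"toy_nh4_e": -1, "toy_nh4_c": 1}, kind="spontaneous", lb=DEFAULT_LB, sub="transport"))
    add(rxn("toy_PYRt", {"toy_pyr_c": -1, "toy_pyr_e": 1}, kind="transport", sub="transport"))
    add(rxn("toy_PRODAt", {"toy_prodA_c": -1, "toy_prodA_e": 1}, kind="transport", sub="transport"))
    add(rxn("toy_PRODBt", {"toy_prodB_c": -1, "toy_prodB_e": 1}, kind="transport", sub="transport"))

    add(rxn("toy_HEX",
            {"toy_glcA_c": -1, "toy_atp_c": -1, "toy_g6p_c": 1, "toy_adp_c": 1, "toy_h_c": 1},
            gpr="toy_g_hex", sub="glycolysis"))
    add(rxn("toy_FRUK",
            {"toy_fruA_c": -1, "toy_atp_c": -1, "toy_g6p_c": 1, "toy_adp_c": 1, "toy_h_c": 1},
            gpr="toy_g_fruk", sub="alternative carbon"))
    add(rxn("toy_EMP",
            {"toy_g6p_c": -1, "toy_adp_c": -2, "toy_pi_c": -2,
             "toy_pep_c": 2, "toy_atp_c": 2, "toy_h2o_c": 2},
            gpr="toy_g_emp", sub="glycolysis"))
    add(rxn("toy_PYK",
            {"toy_pep_c": -1, "toy_adp_c": -1, "toy_h_c": -1, "toy_pyr_c": 1, "toy_atp_c": 1},
            gpr="toy_g_pyk", sub="glycolysis"))
    add(rxn("toy_PPP", {"toy_g6p_c": -1, "toy_e4p_c": 1},
            gpr="toy_g_ppp1 or toy_g_ppp2", sub="pentose phosphate"))
    add(rxn("toy_DAHPS", {"toy_e4p_c": -1, "toy_pep_c": -1, "toy_dahp_c": 1},
            gpr="toy_g_dhsA and toy_g_dhsB", sub="shikimate"))
    add(rxn("toy_SHK1",
            {"toy_dahp_c": -1, "toy_atp_c": -1, "toy_shk_c": 1, "toy_adp_c": 1},
            gpr="toy_g_shk1", sub="shikimate"))
    add(rxn("toy_SHK2", {"toy_shk_c": -1, "toy_cho_c": 1},
            gpr="toy_g_shk2", sub="shikimate"))
    add(rxn("toy_PRODA", {"toy_cho_c": -1, "toy_prodA_c": 1},
            gpr="toy_g_pA", sub="product A"))
    add(rxn("toy_PRODB", {"toy_cho_c": -1, "toy_pep_c": -1, "toy_prodB_c": 1},
            gpr="toy_g_pB", sub="product B"))
    add(rxn("toy_AAS",
            {"toy_pyr_c": -1, "toy_nh4_c": -1, "toy_atp_c": -1,
             "toy_aa_c": 1, "toy_adp_c": 1, "toy_pi_c": 1},
            gpr="toy_g_aa", sub="amino acids"))

    add(rxn("toy_NGAM",
            {"toy_atp_c": -1, "toy_h2o_c": -1, "toy_adp_c": 1, "toy_pi_c": 1, "toy_h_c": 1},
            kind="pseudo", sub="maintenance"))
    g = config.gaec
    add(rxn("toy_BIOMASS",
            {"toy_aa_c": -1.0, "toy_atp_c": -g, "toy_h2o_c": -g,
             "toy_adp_c": g, "toy_pi_c": g, "toy_h_c": g},
            kind="pseudo", sub="biomass"))

    # padding: side chains off pyruvate to a secreted byproduct; they can
    # never pay off energetically, so the optimum is untouched
    n_pad = config.n_reactions - len(reactions)
    if n_pad < 0:
        raise ValueError(f"n_reactions below the {len(reactions)}-reaction core")
    chain_i = 0
    while n_pad >= 3:
        chain_i += 1
        k = int(min(rng.integers(1, 4), n_pad - 2))
        prev = "toy_pyr_c"
        for j in range(1, k + 1):
            mid = f"toy_side{chain_i}_{j}_c"
            mets[mid] = _met(mid, "c")
            add(rxn(f"toy_SIDE{chain_i}_{j}", {prev: -1, mid: 1},
                    gpr=f"toy_g_side{chain_i}_{j}", sub="padding"))
            prev = mid
        out_e = f"toy_side{chain_i}_e"
        mets[out_e] = _met(out_e, "e")
        add(rxn(f"toy_SIDE{chain_i}t", {prev: -1, out_e: 1}, kind="transport", sub="padding"))
        add(rxn(f"EX_toy_side{chain_i}", {out_e: -1.0}, kind="exchange", lb=0.0))
        n_pad -= k + 2

    # designed paralogue structure: toy_PPP is always isozymed; additional
    # isozyme pairs go on padding reactions until the configured fraction
    # of gene-associated reactions is met
    gene_rxns = [r.id for r in reactions.values() if r.gpr is not None]
    want = int(round(config.paralogue_fraction * len(gene_rxns)))
    pad_rxns = sorted(
        r for r in gene_rxns
        if r.startswith("toy_SIDE") and reactions[r].gpr.op == "gene"
    )
    extra = max(want - 1, 0)  # toy_PPP already counts
    for rid in pad_rxns[:extra]:
        old = reactions[rid]
        reactions[rid] = rxn(
            rid, old.stoichiometry,
            gpr=f"{old.gpr.gene} or {old.gpr.gene}B", sub=old.subsystem,
        )
    # additional AND complexes on padding (beyond the designed toy_DAHPS)
    for rid in pad_rxns[extra: extra + config.n_complex_reactions]:
        old = reactions[rid]
        reactions[rid] = rxn(
            rid, old.stoichiometry,
            gpr=f"{old.gpr.gene} and {old.gpr.gene}X", sub=old.subsystem,
        )

    return MetabolicModel(
        id=f"toy_template_{seed}",
        metabolites=mets,
        reactions=reactions,
        objective_reaction_id="toy_BIOMASS",
        compartments={"c": "cytosol", "e": "extracellular"},
    )


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def _target_name(template_gene: str) -> str:
    return template_gene.replace("toy_g_", "toy_t_", 1)


def make_ortholog_hits(
    template_genes: set[str] | frozenset[str],
    dropped: tuple[str, ...] = (),
    degraded: tuple[str, ...] = (),
    seed: int = 0,
) -> tuple[list[HomologyHit], list[HomologyHit], frozenset[tuple[str, str]]]:
    """Reciprocal hit tables plus the surviving-pair ground truth.

    Orthologous genes get hits passing every cutoff in both directions;
    ``degraded`` genes get hits failing exactly one cutoff (rotating which);
    ``dropped`` genes get none.  A couple of one-directional decoy hits
    exercise the bidirectionality requirement.
    """
    rng = np.random.default_rng(seed + 1)
    unknown = (set(dropped) | set(degraded)) - set(template_genes)
    if unknown:
        raise ValueError(f"dropped/degraded genes not in template: {sorted(unknown)}")
    fwd: list[HomologyHit] = []
    rev: list[HomologyHit] = []
    truth: set[tuple[str, str]] = set()
    for i, g in enumerate(sorted(template_genes)):
        if g in dropped:
            continue
        t = _target_name(g)
        ident = float(rng.uniform(45, 95))
        length = int(rng.integers(120, 400))
        evalue = float(10.0 ** -rng.uniform(60, 150))
        if g in degraded:
            fail = i % 3
            f_ident = 39.9 if fail == 0 else ident
            f_len = 60 if fail == 1 else length
            f_eval = 1e-40 if fail == 2 else evalue
            fwd.append(HomologyHit(t, g, f_eval, f_ident, f_len))
            rev.append(HomologyHit(g, t, evalue, ident, length))
            continue
        fwd.append(HomologyHit(t, g, evalue, ident, length))
        rev.append(HomologyHit(g, t, evalue, ident, length))
        truth.add((t, g))
    # decoys: strong forward hit with no reverse support (anchored on a
    # retained gene so dropped genes really have zero hits)
    some = sorted(set(template_genes) - set(dropped))[0]
    fwd.append(HomologyHit("toy_t_decoy", some, 1e-80, 70.0, 200))
    rev.append(HomologyHit(some, "toy_t_decoy2", 1e-80, 70.0, 200))
    return fwd, rev, frozenset(truth)


def write_hit_table(hits: list[HomologyHit], path: str | Path) -> None:
    """Emit hits in the 12-column tabular alignment format."""
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query, h.subject, f"{h.identity:.1f}", str(h.alignment_length),
                    "5", "1", "1", str(h.alignment_length), "1",
                    str(h.alignment_length), f"{h.e_value:.2e}", "200.0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cultivation curves
# ---------------------------------------------------------------------------

def make_cultivation(
    yield_mmol_per_gdw: float = 24.7,
    mu: float = 0.09,
    x0: float = 0.02,
    g0: float = 60.0,
    sigma: float = 0.3,
    dt: float = 6.0,
    horizon: float = 72.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential-growth time course with additive truncated-Gaussian noise.

    ``X(t) = x0 e^{mu t}``; ``G(t) = g0 - Y (X(t) - x0)``; the series
    truncates once glucose is depleted.  Columns match the cultivation CSV
    schema (replicate, time_h, glucose_mmol_per_L, biomass_gDW_per_L).
    """
    if min(yield_mmol_per_gdw, mu, x0, g0, dt, horizon) <= 0:
        raise ValueError("cultivation parameters must be positive")
    rng = np.random.default_rng(seed + 2)
    rows = []
    times = np.arange(0.0, horizon + 1e-9, dt)
    for rep in range(1, n_replicates + 1):
        for t in times:
            x = x0 * np.exp(mu * t)
            g = g0 - yield_mmol_per_gdw * (x - x0)
            if g < 0:
                break
            if sigma > 0:
                x = max(x + rng.normal(0.0, sigma * x0), 0.0)
                g = max(g + rng.normal(0.0, sigma), 0.0)
            rows.append(
                {
                    "replicate": rep, "time_h": float(t),
                    "glucose_mmol_per_L": float(g),
                    "biomass_gDW_per_L": float(x),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delta-G tables
# ---------------------------------------------------------------------------

def make_dg_table(
    model: MetabolicModel, seed: int = 0
) -> tuple[list[DeltaGRecord], dict[str, tuple[float, float] | None]]:
    """Gibbs-energy records over the enzymatic reactions with bound truth.

    The plan covers all four regimes: strongly negative (forward-
    irreversible), strongly positive (reverse-irreversible), in-band
    (reversible), the exact -30 boundary, and unavailable records.
    Expected bounds (None for unavailable) follow the +/-30 kJ/mol rule.
    """
    rng = np.random.default_rng(seed + 3)
    enzymatic = sorted(
        r.id for r in model.reactions.values() if r.kind == "enzymatic"
    )
    records: list[DeltaGRecord] = []
    expected: dict[str, tuple[float, float] | None] = {}
    for i, rid in enumerate(enzymatic):
        regime = i % 5
        if regime == 0:
            dg = float(-rng.uniform(35, 80))
            expected[rid] = (0.0, DEFAULT_UB)
        elif regime == 1:
            dg = float(rng.uniform(35, 80))
            expected[rid] = (DEFAULT_LB, 0.0)
        elif regime == 2:
            dg = float(rng.uniform(-25, 25))
            expected[rid] = (DEFAULT_LB, DEFAULT_UB)
        elif regime == 3:
            dg = -30.0  # boundary: inclusive, counts as irreversible
            expected[rid] = (0.0, DEFAULT_UB)
        else:
            records.append(DeltaGRecord(rid, None, available=False))
            expected[rid] = None
            continue
        records.append(DeltaGRecord(rid, dg, available=True))
    return records, expected


# ---------------------------------------------------------------------------
# full ecosystem
# ---------------------------------------------------------------------------

@dataclass
class EcosystemTruth:
    ortholog_pairs: frozenset[tuple[str, str]]
    draft_reactions: frozenset[str]
    after_transfer_reactions: frozenset[str]
    gapfill_set: frozenset[str]
    final_reactions: frozenset[str]
    essential_genes_template: frozenset[str]
    essential_genes_final: frozenset[str]
    product_pathway_reactions: tuple[str, ...]
    dg_expected_bounds: dict[str, tuple[float, float] | None]


@dataclass
class ToyEcosystem:
    seed: int
    config: ToyConfig
    template: MetabolicModel
    forward_hits: list[HomologyHit]
    reverse_hits: list[HomologyHit]
    heterologous: list[Reaction]
    cultivation: pd.DataFrame
    dg_records: list[DeltaGRecord]
    truth: EcosystemTruth


def _simulate_prune(
    reactions: dict[str, Reaction]
) -> frozenset[str]:
    """Dead-end simulation used only to record the generator's ground truth
    (written independently of the pruning implementation)."""
    alive = dict(reactions)
    changed = True
    while changed:
        changed = False
        users: dict[str, list[str]] = {}
        for r in alive.values():
            for m in r.stoichiometry:
                users.setdefault(m, []).append(r.id)
        for rid in list(alive):
            r = alive[rid]
            if r.kind in ("exchange", "pseudo"):
                continue
            if any(len(users[m]) == 1 for m in r.stoichiometry):
                del alive[rid]
                changed = True
                break
    return frozenset(alive)


def make_ecosystem(seed: int = 0, config: ToyConfig = ToyConfig()) -> ToyEcosystem:
    """Generate template, inputs and ground truth for one seed."""
    template = make_template_model(seed, config)
    fwd, rev, pairs = make_ortholog_hits(
        set(template.genes),
        dropped=config.dropped_genes,
        degraded=config.degraded_genes,
        seed=seed,
    )

    surviving = {s for _, s in pairs}

    # expected draft: template reactions whose GPR is satisfiable with only
    # surviving template genes (computed from the designed GPRs)
    draft = frozenset(
        r.id
        for r in template.reactions.values()
        if r.gpr is not None and r.gpr.evaluate(frozenset(template.genes - surviving))
    )
    nongene = {r.id for r in template.reactions.values() if r.gpr is None}
    after_transfer = _simulate_prune(
        {rid: template.reactions[rid] for rid in draft | nongene}
    )
    gapfill = frozenset(set(_BIOMASS_SUPPORT) - set(after_transfer))
    final = frozenset(after_transfer | gapfill)

    ess_template = frozenset(
        g for rid, g in _CORE_ESSENTIAL.items()
    )
    ess_final = frozenset(
        g if rid in gapfill else _target_name(g)
        for rid, g in _CORE_ESSENTIAL.items()
    )

    heterologous = [
        Reaction(
            id="toy_HET1",
            stoichiometry={"toy_cho_c": -1, "toy_atp_c": -1, "toy_het_c": 1, "toy_adp_c": 1},
            lower_bound=0.0, gpr=parse_gpr("toy_t_het1"), subsystem="heterologous",
        ),
        Reaction(
            id="toy_HETt",
            stoichiometry={"toy_het_c": -1, "toy_het_e": 1},
            lower_bound=0.0, kind="transport", subsystem="heterologous",
        ),
        Reaction(
            id="EX_toy_het",
            stoichiometry={"toy_het_e": -1.0},
            lower_bound=0.0, kind="exchange",
        ),
    ]

    cultivation = make_cultivation(
        config.yield_mmol_per_gdw, config.mu, config.x0, config.g0,
        config.sigma, config.dt, config.horizon, config.n_replicates, seed,
    )
    dg_records, dg_expected = make_dg_table(template, seed)

    truth = EcosystemTruth(
        ortholog_pairs=pairs,
        draft_reactions=draft,
        after_transfer_reactions=frozenset(after_transfer),
        gapfill_set=gapfill,
        final_reactions=final,
        essential_genes_template=ess_template,
        essential_genes_final=ess_final,
        product_pathway_reactions=_PRODUCT_A_PATH,
        dg_expected_bounds=dg_expected,
    )
    return ToyEcosystem(
        seed=seed, config=config, template=template,
        forward_hits=fwd, reverse_hits=rev, heterologous=heterologous,
        cultivation=cultivation, dg_records=dg_records, truth=truth,
    )
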