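"""Homology filtering, reaction transfer, gap-filling and reversibility."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemsmith.fba import solve_fba
from gemsmith.gpr import parse_gpr
from gemsmith.model_core import (
    DEFAULT_LB,
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from gemsmith.reconstruction import (
    DeltaGRecord,
    FilterCutoffs,
    HomologyHit,
    UnfillableError,
    add_reactions_from,
    assign_reversibility,
    draft_from_template,
    filter_orthologs,
    gap_fill,
    gap_fill_substrates,
    genomic_coverage,
    merge_external_reactions,
    read_hit_table,
    transfer_nongene_reactions,
)
from gemsmith.synthetic import make_ecosystem, toy_medium, write_hit_table

from oracles import exhaustive_gap_fill_size


def hit(query="t1", subject="g1", e=1e-60, ident=60.0, length=150):
    return HomologyHit(query, subject, e, ident, length)


class TestCutoffs:
    def test_defaults_pass_strong_hit(self):
        assert FilterCutoffs().passes(hit())

    @pytest.mark.parametrize(
        "kwargs,ok",
        [
            ({"e": 1e-50}, True),     # boundary inclusive
            ({"e": 1e-40}, False),    # too weak
            ({"ident": 40.0}, True),  # boundary inclusive
            ({"ident": 39.9}, False),
            ({"length": 90}, True),   # boundary inclusive
            ({"length": 89}, False),
        ],
    )
    def test_boundaries(self, kwargs, ok):
        assert FilterCutoffs().passes(hit(**kwargs)) is ok


class TestFilterOrthologs:
    def test_requires_both_directions(self):
        fwd = [hit("t1", "g1")]
        rev = []  # no reverse support
        assert len(filter_orthologs(fwd, rev)) == 0
        rev = [hit("g1", "t1")]
        assert ("t1", "g1") in filter_orthologs(fwd, rev)

    def test_generated_tables_reproduce_truth(self, eco):
        got = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        assert got.pairs == eco.truth.ortholog_pairs

    def test_decoys_rejected(self, eco):
        pairs = filter_orthologs(eco.forward_hits, eco.reverse_hits).pairs
        for t, _ in pairs:
            assert "decoy" not in t

    @settings(max_examples=100, deadline=None)
    @given(
        e=st.floats(1e-60, 1e-30),
        ident=st.floats(30.0, 60.0),
        length=st.integers(50, 200),
    )
    def test_loosening_cutoffs_is_monotone(self, eco, e, ident, length):
        tight = FilterCutoffs(min(e, 1e-50), max(length, 90), max(ident, 40.0))
        loose = FilterCutoffs(max(e, 1e-50), min(length, 90), min(ident, 40.0))
        kept_tight = filter_orthologs(
            eco.forward_hits, eco.reverse_hits, tight
        ).pairs
        kept_loose = filter_orthologs(
            eco.forward_hits, eco.reverse_hits, loose
        ).pairs
        assert kept_tight <= kept_loose


class TestHitTable:
    def test_write_read_round_trip(self, tmp_path, eco):
        path = tmp_path / "hits.tsv"
        write_hit_table(eco.forward_hits, path)
        back = read_hit_table(path)
        assert [(h.query, h.subject) for h in back] == [
            (h.query, h.subject) for h in eco.forward_hits
        ]
        for a, b in zip(back, eco.forward_hits):
            assert a.identity == pytest.approx(b.identity, abs=0.05)
            assert a.e_value == pytest.approx(b.e_value, rel=0.01)
            assert a.alignment_length == b.alignment_length

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="bad.tsv:1"):
            read_hit_table(path)

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "# comment\n\n"
            "t1\tg1\t60.0\t150\t5\t1\t1\t150\t1\t150\t1e-60\t200.0\n"
        )
        assert len(read_hit_table(path)) == 1


class TestDraft:
    def template_ab(self):
        mets = {m: Metabolite(m) for m in ("A", "B")}
        rxns = {
            "R_and": Reaction("R_and", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("gA and gB")),
            "R_or": Reaction("R_or", {"A": -1.0, "B": 1.0}, gpr=parse_gpr("gA or gB")),
            "EX_A": Reaction("EX_A", {"A": -1.0}, kind="exchange", lower_bound=-10),
        }
        return MetabolicModel("t", mets, rxns, None)

    def orthologs(self, pairs):
        from gemsmith.reconstruction import OrthologMap

        return OrthologMap(frozenset(pairs))

    def test_and_requires_all_genes(self):
        t = self.template_ab()
        # only gA has an ortholog: AND dies, OR survives via tA
        draft = draft_from_template(t, self.orthologs({("tA", "gA")}))
        assert set(draft.reactions) == {"R_or"}
        assert draft.reactions["R_or"].genes == {"tA"}

    def test_and_rewritten_with_both_genes(self):
        t = self.template_ab()
        draft = draft_from_template(
            t, self.orthologs({("tA", "gA"), ("tB", "gB")})
        )
        gpr = draft.reactions["R_and"].gpr
        assert gpr.evaluate(frozenset()) is True
        assert gpr.evaluate(frozenset({"tA"})) is False

    def test_multiple_orthologs_become_isozymes(self):
        t = self.template_ab()
        draft = draft_from_template(
            t, self.orthologs({("tA1", "gA"), ("tA2", "gA"), ("tB", "gB")})
        )
        gpr = draft.reactions["R_and"].gpr
        # either tA copy suffices alongside tB
        assert gpr.evaluate(frozenset({"tA1"})) is True
        assert gpr.evaluate(frozenset({"tA2"})) is True
        assert gpr.evaluate(frozenset({"tA1", "tA2"})) is False

    def test_geneless_reactions_not_drafted_here(self):
        t = self.template_ab()
        draft = draft_from_template(t, self.orthologs({("tA", "gA")}))
        assert "EX_A" not in draft.reactions

    def test_draft_gpr_leaves_are_target_genes_only(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        targets = {t for t, _ in orthologs.pairs}
        for rxn in draft.reactions.values():
            assert rxn.genes <= targets

    def test_draft_reactions_match_truth(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        assert set(draft.reactions) == set(eco.truth.draft_reactions)


class TestTransfer:
    def test_adopts_objective_and_prunes(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        out = transfer_nongene_reactions(eco.template, draft)
        assert out.objective_reaction_id == "toy_BIOMASS"
        assert set(out.reactions) == set(eco.truth.after_transfer_reactions)

    def test_stoichiometry_conflict_raises(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        clash = eco.template.reactions["toy_GLCt"]
        draft.reactions["toy_GLCt"] = Reaction(
            "toy_GLCt", {"toy_glcA_e": -2.0, "toy_glcA_c": 1.0}
        )
        for m in clash.stoichiometry:
            draft.metabolites.setdefault(m, eco.template.metabolites[m])
        with pytest.raises(ValueError, match="different stoichiometry"):
            transfer_nongene_reactions(eco.template, draft)


class TestGapFill:
    def abc_models(self, extra_template_rxns):
        """Draft that cannot reach C; template offers routes from A."""
        mets = {m: Metabolite(m) for m in ("A", "B", "C")}
        draft_rxns = {
            "EX_A": Reaction("EX_A", {"A": -1.0}, lower_bound=-10.0, kind="exchange"),
            "EX_C": Reaction("EX_C", {"C": -1.0}, lower_bound=0.0, kind="exchange"),
        }
        draft = MetabolicModel("d", dict(mets), dict(draft_rxns), "EX_C")
        t_rxns = dict(draft_rxns)
        t_rxns.update(extra_template_rxns)
        template = MetabolicModel("t", dict(mets), t_rxns, "EX_C")
        return draft, template

    def test_prefers_single_bypass_over_two_step_path(self):
        draft, template = self.abc_models(
            {
                "R1": Reaction("R1", {"A": -1.0, "B": 1.0}),
                "R2": Reaction("R2", {"B": -1.0, "C": 1.0}),
                "R3": Reaction("R3", {"A": -1.0, "C": 1.0}),
            }
        )
        assert gap_fill(draft, template, "EX_C", {"EX_A": 10.0}) == ["R3"]

    def test_two_step_path_when_no_bypass(self):
        draft, template = self.abc_models(
            {
                "R1": Reaction("R1", {"A": -1.0, "B": 1.0}),
                "R2": Reaction("R2", {"B": -1.0, "C": 1.0}),
            }
        )
        assert gap_fill(draft, template, "EX_C", {"EX_A": 10.0}) == ["R1", "R2"]

    def test_lexicographic_tie_break(self):
        draft, template = self.abc_models(
            {
                "R_b": Reaction("R_b", {"A": -1.0, "C": 1.0}),
                "R_a": Reaction("R_a", {"A": -1.0, "C": 1.0}),
            }
        )
        assert gap_fill(draft, template, "EX_C", {"EX_A": 10.0}) == ["R_a"]

    def test_growing_draft_returns_empty(self):
        draft, template = self.abc_models(
            {"R3": Reaction("R3", {"A": -1.0, "C": 1.0})}
        )
        draft.reactions["R3"] = template.reactions["R3"]
        assert gap_fill(draft, template, "EX_C", {"EX_A": 10.0}) == []

    def test_unfillable_raises_with_blocked_precursors(self):
        draft, template = self.abc_models(
            {"R1": Reaction("R1", {"A": -1.0, "B": 1.0})}  # C stays unreachable
        )
        with pytest.raises(UnfillableError) as exc:
            gap_fill(draft, template, "EX_C", {"EX_A": 10.0})
        assert exc.value.blocked_precursors

    def test_cardinality_matches_exhaustive_search(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        draft = transfer_nongene_reactions(eco.template, draft)
        candidates = sorted(set(eco.template.reactions) - set(draft.reactions))
        assert len(candidates) <= 12
        chosen = gap_fill(draft, eco.template, "toy_BIOMASS", toy_medium())
        want = exhaustive_gap_fill_size(
            draft, eco.template, candidates, "toy_BIOMASS", toy_medium()
        )
        assert len(chosen) == want

    def test_minimality_witness(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        draft = transfer_nongene_reactions(eco.template, draft)
        chosen = gap_fill(draft, eco.template, "toy_BIOMASS", toy_medium())
        assert chosen  # the study draft does need filling
        full = add_reactions_from(draft, eco.template, chosen)
        assert solve_fba(full, "toy_BIOMASS", medium=toy_medium()).objective_value >= 1e-3
        for drop in chosen:
            partial = add_reactions_from(
                draft, eco.template, [r for r in chosen if r != drop]
            )
            sol = solve_fba(partial, "toy_BIOMASS", medium=toy_medium())
            assert not sol.optimal or sol.objective_value < 1e-3

    def test_matches_generator_truth(self, eco):
        orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
        draft = draft_from_template(eco.template, orthologs)
        draft = transfer_nongene_reactions(eco.template, draft)
        chosen = gap_fill(draft, eco.template, "toy_BIOMASS", toy_medium())
        assert set(chosen) == set(eco.truth.gapfill_set)


class TestSubstrateGapFill:
    def test_fructose_requires_its_kinase_and_transporter(self, reconstructed, eco):
        # start from a reconstruction that never acquired the fructose path
        base = reconstructed.copy()
        for rid in ("toy_FRUK", "toy_FRUt", "EX_toy_fruA"):
            base.reactions.pop(rid, None)
        out, added = gap_fill_substrates(
            base,
            eco.template,
            ["EX_toy_fruA"],
            toy_medium(),
            carbon_exchange="EX_toy_glcA",
        )
        assert set(added["EX_toy_fruA"]) == {"toy_FRUK", "toy_FRUt"}
        medium = {k: v for k, v in toy_medium().items() if k != "EX_toy_glcA"}
        medium["EX_toy_fruA"] = 1.0
        assert solve_fba(out, "toy_BIOMASS", medium=medium).objective_value > 1e-3


class TestMerge:
    def test_new_pathway_added_with_metabolites(self, reconstructed, eco):
        merged, skipped = merge_external_reactions(reconstructed, eco.heterologous)
        assert skipped == []
        for rxn in eco.heterologous:
            assert rxn.id in merged.reactions
        assert "toy_het_c" in merged.metabolites

    def test_gene_overlap_skipped(self, reconstructed):
        rxn = Reaction(
            "toy_NEW",
            {"toy_pyr_c": -1.0, "toy_new_c": 1.0},
            gpr=parse_gpr(sorted(reconstructed.genes)[0]),
        )
        merged, skipped = merge_external_reactions(reconstructed, [rxn])
        assert skipped == ["toy_NEW"]
        assert "toy_NEW" not in merged.reactions

    def test_duplicate_id_same_stoichiometry_skipped(self, reconstructed):
        existing = reconstructed.reactions["toy_GLCt"]
        merged, skipped = merge_external_reactions(
            reconstructed,
            [Reaction("toy_GLCt", dict(existing.stoichiometry))],
        )
        assert skipped == ["toy_GLCt"]

    def test_conflicting_stoichiometry_raises(self, reconstructed):
        with pytest.raises(ValueError, match="conflicts"):
            merge_external_reactions(
                reconstructed,
                [Reaction("toy_GLCt", {"toy_glcA_e": -2.0, "toy_glcA_c": 1.0})],
            )


class TestReversibility:
    def model_r(self):
        mets = {m: Metabolite(m) for m in ("A", "B")}
        rxns = {
            rid: Reaction(rid, {"A": -1.0, "B": 1.0}, lower_bound=DEFAULT_LB)
            for rid in ("R1", "R2", "R3", "R4", "R5")
        }
        return MetabolicModel("m", mets, rxns, None)

    def test_assignment_rules(self):
        m = self.model_r()
        records = [
            DeltaGRecord("R1", -45.0),
            DeltaGRecord("R2", -10.0),
            DeltaGRecord("R3", 45.0),
            DeltaGRecord("R4", -30.0),  # boundary, inclusive
            DeltaGRecord("R5", None, available=False),
        ]
        out, manual = assign_reversibility(m, records)
        assert (out.reactions["R1"].lower_bound, out.reactions["R1"].upper_bound) == (0.0, DEFAULT_UB)
        assert (out.reactions["R2"].lower_bound, out.reactions["R2"].upper_bound) == (DEFAULT_LB, DEFAULT_UB)
        assert (out.reactions["R3"].lower_bound, out.reactions["R3"].upper_bound) == (DEFAULT_LB, 0.0)
        assert (out.reactions["R4"].lower_bound, out.reactions["R4"].upper_bound) == (0.0, DEFAULT_UB)
        # unavailable: untouched, queued for curation
        assert (out.reactions["R5"].lower_bound, out.reactions["R5"].upper_bound) == (DEFAULT_LB, DEFAULT_UB)
        assert manual == ["R5"]

    def test_idempotent(self):
        m = self.model_r()
        records = [DeltaGRecord("R1", -45.0), DeltaGRecord("R3", 45.0)]
        once, _ = assign_reversibility(m, records)
        twice, _ = assign_reversibility(once, records)
        for rid in ("R1", "R3"):
            assert once.reactions[rid].lower_bound == twice.reactions[rid].lower_bound
            assert once.reactions[rid].upper_bound == twice.reactions[rid].upper_bound

    def test_unknown_reaction_raises(self):
        with pytest.raises(KeyError):
            assign_reversibility(self.model_r(), [DeltaGRecord("NOPE", -45.0)])

    def test_generated_table_matches_truth(self, eco):
        out, manual = assign_reversibility(eco.template, eco.dg_records)
        for rid, expected in eco.truth.dg_expected_bounds.items():
            if expected is None:
                assert rid in manual
                continue
            got = (out.reactions[rid].lower_bound, out.reactions[rid].upper_bound)
            assert got == expected, rid


class TestCoverage:
    def test_fraction(self):
        assert genomic_coverage(1, 4) == 25.0

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            genomic_coverage(5, 4)
        with pytest.raises(ValueError):
            genomic_coverage(1, 0)
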