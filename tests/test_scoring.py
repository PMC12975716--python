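"""Rubric engine: published point values, proportional credit, invariants."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellscribe import (
    BiologicalContext,
    ClusterEvidence,
    MarkerEntry,
    RubricConfig,
    score_candidate,
    score_context,
    score_marker_profile,
    score_pathway_profile,
)
from cellscribe.evidence import significant_enrichment
from cellscribe.scoring import (
    CONTEXT_IMPLAUSIBLE,
    CONTEXT_STATE,
    CONTEXT_TYPE,
    MARKER_MATCH,
    NARROW_MARKER,
    NEGATIVE_MARKER,
    PATHWAY_CONFLICT,
    PATHWAY_SHARED,
    PATHWAY_STATE,
    PATHWAY_TYPE,
    SHARED_MARKER,
)

B_CELL = MarkerEntry(
    cell_type_name="B cell",
    broad_markers={"CD19", "MS4A1", "CD79A"},
    narrow_markers={"CD79B", "TCL1A"},
    negative_markers={"CD3D"},
    plausible_tissues={"blood"},
    plausible_states={"naive", "memory@blood"},
    pathways_type={"B cell receptor signaling"},
    pathways_state={"antigen presentation"},
)
T_CELL = MarkerEntry(
    cell_type_name="T cell",
    broad_markers={"CD3D", "CD3E", "CD19"},  # CD19 shared with B cell on purpose
    plausible_tissues={"blood"},
    pathways_type={"T cell receptor signaling"},
)


def points(items, criterion):
    return next(i.points for i in items if i.criterion == criterion)


class TestMarkerProfile:
    def test_full_broad_match_awards_cap(self):
        ev = ClusterEvidence.from_genes("c0", ["CD19", "MS4A1", "CD79A", "GBG0001"])
        items = score_marker_profile(ev, B_CELL)
        assert points(items, MARKER_MATCH) == 45
        assert points(items, NARROW_MARKER) == 0
        assert points(items, SHARED_MARKER) == 0
        assert points(items, NEGATIVE_MARKER) == 0

    def test_full_narrow_match_awards_cap(self):
        ev = ClusterEvidence.from_genes("c0", ["CD79B", "TCL1A"])
        items = score_marker_profile(ev, B_CELL)
        assert points(items, NARROW_MARKER) == 15
        assert points(items, MARKER_MATCH) == 0

    def test_empty_topdeg_scores_zero(self):
        ev = ClusterEvidence.from_genes("c0", [])
        items = score_marker_profile(ev, B_CELL)
        assert all(i.points == 0 for i in items)

    def test_negative_marker_alone_deducts_30(self):
        ev = ClusterEvidence.from_genes("c0", ["CD3D"])
        items = score_marker_profile(ev, B_CELL)
        assert points(items, NEGATIVE_MARKER) == -30
        assert sum(i.points for i in items) == -30

    def test_half_broad_match_rounds_half_up(self):
        entry = MarkerEntry(
            cell_type_name="x", broad_markers={"A1", "A2", "A3", "A4"}
        )
        ev = ClusterEvidence.from_genes("c0", ["A1", "A2"])
        items = score_marker_profile(ev, entry)
        assert points(items, MARKER_MATCH) == 23  # 45 × 2/4 = 22.5 → 23

    def test_shared_marker_deduction_fires_once(self):
        # CD19 matched for B cell and also a positive marker of T cell
        ev = ClusterEvidence.from_genes("c0", ["CD19", "MS4A1", "CD79A"])
        items = score_marker_profile(ev, B_CELL, shortlist=[T_CELL])
        assert points(items, SHARED_MARKER) == -10

    def test_entry_with_no_broad_markers_gets_zero_match(self):
        entry = MarkerEntry(cell_type_name="x", narrow_markers={"N1"})
        ev = ClusterEvidence.from_genes("c0", ["N1", "G2"])
        items = score_marker_profile(ev, entry)
        assert points(items, MARKER_MATCH) == 0
        assert points(items, NARROW_MARKER) == 15


class TestPathwayProfile:
    def enrichment(self, *terms):
        return [significant_enrichment(t) for t in terms]

    def test_all_state_pathways_matched_awards_cap(self):
        ev = ClusterEvidence.from_genes(
            "c0", [], enrichment=self.enrichment("antigen presentation")
        )
        items = score_pathway_profile(ev, B_CELL)
        assert points(items, PATHWAY_STATE) == 15

    def test_type_pathway_cap_is_5(self):
        ev = ClusterEvidence.from_genes(
            "c0", [], enrichment=self.enrichment("B cell receptor signaling")
        )
        items = score_pathway_profile(ev, B_CELL)
        assert points(items, PATHWAY_TYPE) == 5

    def test_absent_enrichment_means_operation_is_skipped(self):
        ev = ClusterEvidence.from_genes("c0", [])
        with pytest.raises(ValueError, match="two-component"):
            score_pathway_profile(ev, B_CELL)

    def test_conflicting_pathway_deducts_20(self):
        # significant term characteristic of the competitor only
        ev = ClusterEvidence.from_genes(
            "c0", [], enrichment=self.enrichment("T cell receptor signaling")
        )
        items = score_pathway_profile(ev, B_CELL, shortlist=[T_CELL])
        assert points(items, PATHWAY_CONFLICT) == -20
        assert points(items, PATHWAY_SHARED) == 0

    def test_shared_pathway_deducts_10_not_conflict(self):
        competitor = MarkerEntry(
            cell_type_name="plasma cell", pathways_state={"antigen presentation"}
        )
        ev = ClusterEvidence.from_genes(
            "c0", [], enrichment=self.enrichment("antigen presentation")
        )
        items = score_pathway_profile(ev, B_CELL, shortlist=[competitor])
        assert points(items, PATHWAY_SHARED) == -10
        assert points(items, PATHWAY_CONFLICT) == 0

    def test_non_significant_terms_are_ignored(self):
        weak = [significant_enrichment("antigen presentation", adjusted_p=0.5)]
        ev = ClusterEvidence.from_genes("c0", [], enrichment=weak)
        items = score_pathway_profile(ev, B_CELL)
        assert all(i.points == 0 for i in items)


class TestContext:
    def test_plausible_tissue_awards_type_points(self):
        items = score_context(B_CELL, BiologicalContext(tissue="blood"))
        assert points(items, CONTEXT_TYPE) == 10
        assert points(items, CONTEXT_IMPLAUSIBLE) == 0

    def test_empty_context_is_vacuously_plausible(self):
        items = score_context(B_CELL, BiologicalContext())
        assert points(items, CONTEXT_TYPE) == 10
        assert points(items, CONTEXT_STATE) == 0
        assert points(items, CONTEXT_IMPLAUSIBLE) == 0

    def test_implausible_tissue_deducts_30(self):
        items = score_context(B_CELL, BiologicalContext(tissue="liver"))
        assert points(items, CONTEXT_IMPLAUSIBLE) == -30
        assert points(items, CONTEXT_TYPE) == 0

    def test_state_points_require_compatible_state_tag(self):
        in_blood = score_context(B_CELL, BiologicalContext(tissue="blood"))
        assert points(in_blood, CONTEXT_STATE) == 10  # 'naive' untagged, 'memory@blood'
        entry = MarkerEntry(
            cell_type_name="x",
            plausible_tissues={"blood", "liver"},
            plausible_states={"regenerating@liver"},
        )
        wrong_tissue = score_context(entry, BiologicalContext(tissue="blood"))
        assert points(wrong_tissue, CONTEXT_STATE) == 0


class TestScoreCandidate:
    def test_maxed_evidence_totals_100(self):
        ev = ClusterEvidence.from_genes(
            "c0",
            ["CD19", "MS4A1", "CD79A", "CD79B", "TCL1A"],
            enrichment=[
                significant_enrichment("antigen presentation"),
                significant_enrichment("B cell receptor signaling"),
            ],
            context=BiologicalContext(tissue="blood"),
        )
        breakdown = score_candidate(ev, B_CELL)
        assert breakdown.total == 100  # 45+15+15+5+10+10
        assert breakdown.marker_component == 60
        assert breakdown.pathway_component == 20
        assert breakdown.context_component == 20

    def test_empty_evidence_empty_context_totals_10(self):
        ev = ClusterEvidence.from_genes("c0", [], context=BiologicalContext())
        breakdown = score_candidate(ev, B_CELL)
        assert breakdown.total == 10  # vacuous context-type points only

    def test_two_component_path_has_no_pathway_items(self):
        ev = ClusterEvidence.from_genes(
            "c0",
            ["CD19", "MS4A1", "CD79A"],
            context=BiologicalContext(tissue="blood"),
        )
        breakdown = score_candidate(ev, B_CELL)
        assert breakdown.pathway_component is None
        assert breakdown.total == 45 + 10 + 10
        pathway_criteria = {PATHWAY_STATE, PATHWAY_TYPE, PATHWAY_SHARED, PATHWAY_CONFLICT}
        assert not {i.criterion for i in breakdown.items} & pathway_criteria

    def test_scoring_is_pure(self):
        ev = ClusterEvidence.from_genes(
            "c0", ["CD19", "CD3D"], context=BiologicalContext(tissue="blood")
        )
        assert score_candidate(ev, B_CELL, [T_CELL]) == score_candidate(ev, B_CELL, [T_CELL])


GENE_POOL = ["CD19", "MS4A1", "CD79A", "CD79B", "TCL1A", "CD3D", "G1", "G2", "G3"]


class TestRubricInvariants:
    @settings(max_examples=150, deadline=None)
    @given(
        degs=st.sets(st.sampled_from(GENE_POOL)),
        tissue=st.sampled_from(["", "blood", "liver"]),
        with_enrichment=st.booleans(),
    )
    def test_bounds_and_conservation(self, degs, tissue, with_enrichment):
        enrichment = (
            [significant_enrichment("antigen presentation"),
             significant_enrichment("T cell receptor signaling")]
            if with_enrichment
            else None
        )
        ev = ClusterEvidence.from_genes(
            "c0", sorted(degs), enrichment=enrichment,
            context=BiologicalContext(tissue=tissue),
        )
        config = RubricConfig()
        breakdown = score_candidate(ev, B_CELL, [T_CELL], config=config)
        assert config.min_total <= breakdown.total <= config.max_total
        assert -100 <= breakdown.total <= 100
        assert sum(i.points for i in breakdown.items) == breakdown.total
        caps = {
            MARKER_MATCH: (0, config.marker_match_max),
            NARROW_MARKER: (0, config.narrow_marker_max),
            SHARED_MARKER: (config.shared_marker_deduction, 0),
            NEGATIVE_MARKER: (config.negative_marker_deduction, 0),
            PATHWAY_STATE: (0, config.pathway_state_max),
            PATHWAY_TYPE: (0, config.pathway_type_max),
            PATHWAY_SHARED: (config.pathway_shared_deduction, 0),
            PATHWAY_CONFLICT: (config.pathway_conflict_deduction, 0),
            CONTEXT_TYPE: (0, config.context_type_max),
            CONTEXT_STATE: (0, config.context_state_max),
            CONTEXT_IMPLAUSIBLE: (config.context_implausible_deduction, 0),
        }
        for item in breakdown.items:
            lo, hi = caps[item.criterion]
            assert lo <= item.points <= hi

    @settings(max_examples=100, deadline=None)
    @given(degs=st.sets(st.sampled_from(GENE_POOL)))
    def test_adding_matched_broad_marker_never_decreases_total(self, degs):
        # no competitors: cross-candidate sharing can legitimately offset gains
        missing = B_CELL.broad_markers - degs
        if not missing:
            return
        ev_before = ClusterEvidence.from_genes("c0", sorted(degs))
        ev_after = ClusterEvidence.from_genes("c0", sorted(degs | {min(missing)}))
        assert score_candidate(ev_after, B_CELL).total >= score_candidate(ev_before, B_CELL).total

    @settings(max_examples=100, deadline=None)
    @given(degs=st.sets(st.sampled_from(GENE_POOL)))
    def test_adding_negative_marker_never_increases_total(self, degs):
        degs = degs - {"CD3D"}
        ev_before = ClusterEvidence.from_genes("c0", sorted(degs))
        ev_after = ClusterEvidence.from_genes("c0", sorted(degs | {"CD3D"}))
        assert score_candidate(ev_after, B_CELL).total <= score_candidate(ev_before, B_CELL).total

    def test_config_rejects_sign_violations(self):
        with pytest.raises(ValueError):
            RubricConfig(marker_match_max=-1)
        with pytest.raises(ValueError):
            RubricConfig(negative_marker_deduction=5)

    def test_default_config_is_the_published_rubric(self):
        config = RubricConfig()
        assert dataclasses.asdict(config) == {
            "marker_match_max": 45,
            "narrow_marker_max": 15,
            "shared_marker_deduction": -10,
            "negative_marker_deduction": -30,
            "pathway_state_max": 15,
            "pathway_type_max": 5,
            "pathway_shared_deduction": -10,
            "pathway_conflict_deduction": -20,
            "context_type_max": 10,
            "context_state_max": 10,
            "context_implausible_deduction": -30,
            "significance": 0.05,
        }
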