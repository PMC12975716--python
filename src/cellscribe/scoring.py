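"""Deterministic cell-type scoring rubric with itemized breakdowns.

The rubric turns the three evidence streams — marker genes, pathway
enrichment, biological context — into an auditable point total for each
candidate cell type.  Concordant evidence earns positive points up to a
per-criterion cap; conflicting evidence triggers fixed one-shot deductions.
Under the default configuration a total lies in [−100, +100].

Two scoring paths exist: the three-component score (marker + pathway +
context) when enrichment results are available, and the two-component score
(marker + context) when they are not; the pathway criteria are then absent
from the breakdown, not zeroed.

Positive criteria award proportional credit: e.g. a candidate with 2 of its
4 broad markers among the cluster's top DEGs earns 45 × 2/4 = 22.5, rounded
half-up to 23.  Deductions are fixed one-shot penalties, applied at most
once per criterion however many genes or terms trigger them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

from .evidence import DEFAULT_SIGNIFICANCE, ClusterEvidence
from .knowledge import BiologicalContext, MarkerEntry, normalize_label

# criterion identifiers, in rubric order
MARKER_MATCH = "marker_match"
NARROW_MARKER = "narrow_marker"
SHARED_MARKER = "shared_marker"
NEGATIVE_MARKER = "negative_marker"
PATHWAY_STATE = "pathway_state"
PATHWAY_TYPE = "pathway_type"
PATHWAY_SHARED = "pathway_shared"
PATHWAY_CONFLICT = "pathway_conflict"
CONTEXT_TYPE = "context_type"
CONTEXT_STATE = "context_state"
CONTEXT_IMPLAUSIBLE = "context_implausible"


@dataclass(frozen=True)
class RubricConfig:
    """Point caps and deductions for every rubric criterion.

    Defaults are the published rubric: maxima are the largest positive
    contribution a criterion can award (proportional credit below it);
    deductions are fixed penalties applied once when triggered.
    """

    marker_match_max: int = 45
    narrow_marker_max: int = 15
    shared_marker_deduction: int = -10
    negative_marker_deduction: int = -30
    pathway_state_max: int = 15
    pathway_type_max: int = 5
    pathway_shared_deduction: int = -10
    pathway_conflict_deduction: int = -20
    context_type_max: int = 10
    context_state_max: int = 10
    context_implausible_deduction: int = -30
    significance: float = DEFAULT_SIGNIFICANCE

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name.endswith("_max") and value < 0:
                raise ValueError(f"{f.name} must be ≥ 0, got {value}")
            if f.name.endswith("_deduction") and value > 0:
                raise ValueError(f"{f.name} must be ≤ 0, got {value}")

    @property
    def min_total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self) if f.name.endswith("_deduction"))

    @property
    def max_total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self) if f.name.endswith("_max"))


DEFAULT_RUBRIC = RubricConfig()


@dataclass(frozen=True)
class CriterionScore:
    """Points for one rubric criterion plus the evidence items that fired it."""

    criterion: str
    points: int
    evidence: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"criterion": self.criterion, "points": self.points, "evidence": list(self.evidence)}


@dataclass(frozen=True)
class ScoreBreakdown:
    """Itemized rubric outcome for one candidate — the transparency artifact.

    ``pathway_component`` is None on the two-component path; the total always
    equals the sum of the itemized criterion points (conservation).
    """

    candidate: str
    items: tuple[CriterionScore, ...]
    marker_component: int
    pathway_component: Optional[int]
    context_component: int
    total: int

    def __post_init__(self) -> None:
        if sum(i.points for i in self.items) != self.total:
            raise ValueError("breakdown items do not sum to total")
        components = self.marker_component + self.context_component + (self.pathway_component or 0)
        if components != self.total:
            raise ValueError("components do not sum to total")

    def item(self, criterion: str) -> Optional[CriterionScore]:
        for entry in self.items:
            if entry.criterion == criterion:
                return entry
        return None

    def points(self, criterion: str) -> Optional[int]:
        entry = self.item(criterion)
        return entry.points if entry is not None else None

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "items": [i.to_dict() for i in self.items],
            "marker_component": self.marker_component,
            "pathway_component": self.pathway_component,
            "context_component": self.context_component,
            "total": self.total,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreBreakdown":
        return cls(
            candidate=d["candidate"],
            items=tuple(
                CriterionScore(i["criterion"], int(i["points"]), tuple(i.get("evidence", ())))
                for i in d["items"]
            ),
            marker_component=int(d["marker_component"]),
            pathway_component=None if d["pathway_component"] is None else int(d["pathway_component"]),
            context_component=int(d["context_component"]),
            total=int(d["total"]),
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _proportional(cap: int, matched: int, declared: int) -> int:
    if declared == 0:
        return 0
    return min(cap, _round_half_up(cap * matched / declared))


def score_marker_profile(
    evidence: ClusterEvidence,
    entry: MarkerEntry,
    shortlist: Sequence[MarkerEntry] = (),
    config: RubricConfig = DEFAULT_RUBRIC,
) -> list[CriterionScore]:
    """Marker-profile criteria: broad match, narrow match, shared, negative.

    ``shortlist`` holds the *other* candidates under consideration for this
    cluster; a matched marker that is also a positive marker of one of them
    triggers the shared-marker deduction once.
    """
    top = frozenset(evidence.degs)
    broad_hit = sorted(entry.broad_markers & top)
    narrow_hit = sorted(entry.narrow_markers & top)
    items = [
        CriterionScore(
            MARKER_MATCH,
            _proportional(config.marker_match_max, len(broad_hit), len(entry.broad_markers)),
            tuple(broad_hit),
        ),
        CriterionScore(
            NARROW_MARKER,
            _proportional(config.narrow_marker_max, len(narrow_hit), len(entry.narrow_markers)),
            tuple(narrow_hit),
        ),
    ]
    matched = set(broad_hit) | set(narrow_hit)
    others = [o for o in shortlist if o.cell_type_name != entry.cell_type_name]
    shared = sorted(
        g for g in matched if any(g in other.positive_markers for other in others)
    )
    items.append(
        CriterionScore(
            SHARED_MARKER, config.shared_marker_deduction if shared else 0, tuple(shared)
        )
    )
    negative_hit = sorted(entry.negative_markers & top)
    items.append(
        CriterionScore(
            NEGATIVE_MARKER,
            config.negative_marker_deduction if negative_hit else 0,
            tuple(negative_hit),
        )
    )
    return items


def score_pathway_profile(
    evidence: ClusterEvidence,
    entry: MarkerEntry,
    shortlist: Sequence[MarkerEntry] = (),
    config: RubricConfig = DEFAULT_RUBRIC,
) -> list[CriterionScore]:
    """Pathway-profile criteria on significant enriched terms.

    Callers must not invoke this when ``evidence.enrichment`` is None — the
    two-component path skips the pathway component entirely.

    A conflicting pathway is a significant term characteristic of a
    shortlisted competitor but *not* of this entry (competitor-exclusive);
    a shared pathway is a matched term that another candidate also claims.
    """
    if evidence.enrichment is None:
        raise ValueError("pathway scoring requires enrichment results (two-component path skips it)")
    significant = evidence.significant_terms(config.significance)
    state_hit = sorted(entry.pathways_state & significant)
    type_hit = sorted(entry.pathways_type & significant)
    items = [
        CriterionScore(
            PATHWAY_STATE,
            _proportional(config.pathway_state_max, len(state_hit), len(entry.pathways_state)),
            tuple(state_hit),
        ),
        CriterionScore(
            PATHWAY_TYPE,
            _proportional(config.pathway_type_max, len(type_hit), len(entry.pathways_type)),
            tuple(type_hit),
        ),
    ]
    others = [o for o in shortlist if o.cell_type_name != entry.cell_type_name]
    matched = set(state_hit) | set(type_hit)
    shared = sorted(
        t for t in matched if any(t in other.characteristic_pathways for other in others)
    )
    items.append(
        CriterionScore(
            PATHWAY_SHARED, config.pathway_shared_deduction if shared else 0, tuple(shared)
        )
    )
    conflicts = sorted(
        t
        for t in significant - entry.characteristic_pathways
        if any(t in other.characteristic_pathways for other in others)
    )
    items.append(
        CriterionScore(
            PATHWAY_CONFLICT,
            config.pathway_conflict_deduction if conflicts else 0,
            tuple(conflicts),
        )
    )
    return items


def score_context(
    entry: MarkerEntry,
    context: BiologicalContext,
    config: RubricConfig = DEFAULT_RUBRIC,
) -> list[CriterionScore]:
    """Biological-context criteria: type plausibility, state plausibility,
    implausibility deduction.

    An empty tissue is vacuously plausible (type points awarded, deduction
    never fires); state points require a non-empty context and a declared
    state compatible with it.
    """
    tissue = normalize_label(context.tissue)
    tissues = {normalize_label(t) for t in entry.plausible_tissues}
    plausible = not tissue or tissue in tissues
    items = [
        CriterionScore(
            CONTEXT_TYPE,
            config.context_type_max if plausible else 0,
            (context.tissue or "unrestricted",) if plausible else (),
        )
    ]
    state = None if context.is_empty else entry.plausible_state_for(context.tissue, context.condition)
    items.append(
        CriterionScore(
            CONTEXT_STATE,
            config.context_state_max if state is not None else 0,
            (state,) if state is not None else (),
        )
    )
    items.append(
        CriterionScore(
            CONTEXT_IMPLAUSIBLE,
            0 if plausible else config.context_implausible_deduction,
            () if plausible else (context.tissue,),
        )
    )
    return items


def score_candidate(
    evidence: ClusterEvidence,
    entry: MarkerEntry,
    shortlist: Sequence[MarkerEntry] = (),
    context: Optional[BiologicalContext] = None,
    config: RubricConfig = DEFAULT_RUBRIC,
) -> ScoreBreakdown:
    """Full rubric score for one candidate against one cluster's evidence.

    Uses the three-component score when enrichment results are present and
    the two-component (marker + context) score when they are absent.
    """
    context = context if context is not None else evidence.context
    marker_items = score_marker_profile(evidence, entry, shortlist, config)
    pathway_items: list[CriterionScore] = []
    pathway_component: Optional[int] = None
    if evidence.enrichment is not None:
        pathway_items = score_pathway_profile(evidence, entry, shortlist, config)
        pathway_component = sum(i.points for i in pathway_items)
    context_items = score_context(entry, context, config)
    items = tuple(marker_items + pathway_items + context_items)
    return ScoreBreakdown(
        candidate=entry.cell_type_name,
        items=items,
        marker_component=sum(i.points for i in marker_items),
        pathway_component=pathway_component,
        context_component=sum(i.points for i in context_items),
        total=sum(i.points for i in items),
    )
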