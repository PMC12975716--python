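"""Three-stage annotation pipeline: Prospector → Insightor → Reviewer.

The Prospector drafts a shortlist of cell types plausible in the supplied
tissue context ("step back" before deciding); the Insightor scores every
shortlisted candidate against the cluster's evidence through a pluggable
reasoning backend; the Reviewer ranks the candidates, keeps exactly three,
assigns confidence tiers and flags clusters whose top two candidates are too
close to call.

Backends implement :class:`Backend`.  The reference backend is the
deterministic rubric engine; :class:`CompletionBackend` adapts any
text-completion callable (an LLM endpoint, say) behind a strict JSON
request/response schema, and :class:`ReplayTransport` answers requests from
a recorded fixture only — it fails loudly on a cache miss, so tests can
exercise the adapter without network access or keys.

Clusters are embarrassingly parallel: ``annotate_all`` may fan out over a
thread pool, but results are assembled in cluster-id order and per-cluster
failures are isolated, so serial and concurrent runs produce identical
reports.
"""

from __future__ import annotations

import abc
import hashlib
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .evidence import (
    DEFAULT_TOP_N,
    ClusterEvidence,
    CountsWithClusters,
    GeneSetCollection,
    extract_evidence,
    rank_markers,
    ora_enrich,
)
from .knowledge import BiologicalContext, MarkerEntry, MarkerKnowledgeBase, normalize_label
from .scoring import DEFAULT_RUBRIC, RubricConfig, ScoreBreakdown, score_candidate

logger = logging.getLogger("cellscribe")


class PipelineError(RuntimeError):
    """Unrecoverable, input-level pipeline failure."""


class BackendError(RuntimeError):
    """A reasoning backend failed or returned malformed output."""


class ReplayMissError(BackendError):
    """The replay transport has no recording for the request."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables for a full annotation run, echoed into the report metadata."""

    top_n: int = DEFAULT_TOP_N
    shortlist_limit: int = 10
    low_agreement_margin: int = 10
    high_threshold: int = 70
    medium_threshold: int = 40
    rubric: RubricConfig = field(default_factory=RubricConfig)
    backend: str = "rubric"
    n_jobs: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        # n_jobs is execution mechanics, not part of the scientific config:
        # serial and concurrent runs must serialize identically
        d = {
            "top_n": self.top_n,
            "shortlist_limit": self.shortlist_limit,
            "low_agreement_margin": self.low_agreement_margin,
            "high_threshold": self.high_threshold,
            "medium_threshold": self.medium_threshold,
            "backend": self.backend,
            "seed": self.seed,
            "rubric": {k: getattr(self.rubric, k) for k in (
                "marker_match_max", "narrow_marker_max", "shared_marker_deduction",
                "negative_marker_deduction", "pathway_state_max", "pathway_type_max",
                "pathway_shared_deduction", "pathway_conflict_deduction",
                "context_type_max", "context_state_max", "context_implausible_deduction",
                "significance",
            )},
        }
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def tier(self, total: int) -> str:
        if total >= self.high_threshold:
            return "high"
        if total >= self.medium_threshold:
            return "medium"
        return "low"


@dataclass(frozen=True)
class CandidateShortlist:
    """Plausible cell types for one cluster, with a provenance note each."""

    cluster_id: str
    names: tuple[str, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise PipelineError(f"shortlist for {self.cluster_id!r} contains duplicates")


@dataclass(frozen=True)
class CellTypeCandidate:
    """One scored candidate: identity, state, evidence and breakdown."""

    name: str
    cl_id: Optional[str]
    state: str
    key_markers: tuple[str, ...]
    breakdown: ScoreBreakdown
    confidence: str = ""
    validation_markers: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return self.breakdown.total

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cl_id": self.cl_id,
            "state": self.state,
            "key_markers": list(self.key_markers),
            "breakdown": self.breakdown.to_dict(),
            "confidence": self.confidence,
            "validation_markers": list(self.validation_markers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTypeCandidate":
        allowed = {"name", "cl_id", "state", "key_markers", "breakdown", "confidence", "validation_markers"}
        unknown = set(d) - allowed
        if unknown:
            raise BackendError(f"unknown candidate fields: {sorted(unknown)}")
        return cls(
            name=str(d["name"]),
            cl_id=d.get("cl_id"),
            state=str(d.get("state", "")),
            key_markers=tuple(d.get("key_markers", ())),
            breakdown=ScoreBreakdown.from_dict(d["breakdown"]),
            confidence=str(d.get("confidence", "")),
            validation_markers=tuple(d.get("validation_markers", ())),
        )


class Backend(abc.ABC):
    """Reasoning-backend contract: score a shortlist against cluster evidence.

    A backend declaring ``deterministic = True`` must be bit-for-bit
    reproducible for identical inputs.
    """

    name: str = "backend"
    deterministic: bool = False

    @abc.abstractmethod
    def score_shortlist(
        self,
        shortlist: CandidateShortlist,
        evidence: ClusterEvidence,
        context: BiologicalContext,
        kb: MarkerKnowledgeBase,
        config: RubricConfig,
    ) -> list[CellTypeCandidate]:
        ...


def _candidate_from_entry(
    entry: MarkerEntry,
    breakdown: ScoreBreakdown,
    evidence: ClusterEvidence,
    context: BiologicalContext,
) -> CellTypeCandidate:
    top = frozenset(evidence.degs)
    return CellTypeCandidate(
        name=entry.cell_type_name,
        cl_id=entry.cl_id,
        state=entry.plausible_state_for(context.tissue, context.condition) or "",
        key_markers=tuple(sorted(entry.positive_markers & top)),
        breakdown=breakdown,
        validation_markers=tuple(sorted(entry.positive_markers - top)),
    )


class RubricBackend(Backend):
    """Reference backend: the deterministic scoring rubric, no language model."""

    name = "rubric"
    deterministic = True

    def score_shortlist(self, shortlist, evidence, context, kb, config):
        entries = [kb.get(name) for name in shortlist.names]
        out = []
        for entry in entries:
            others = [e for e in entries if e is not entry]
            breakdown = score_candidate(evidence, entry, others, context, config)
            out.append(_candidate_from_entry(entry, breakdown, evidence, context))
        out.sort(key=lambda c: (-c.total, c.name))
        return out


class CompletionBackend(Backend):
    """Adapter for text-completion endpoints behind a strict JSON schema.

    ``transport`` maps a request string to a completion string.  The request
    is canonical JSON carrying the shortlist, the cluster evidence, the
    context and the rubric; the completion must be a JSON object
    ``{"candidates": [...]}`` whose items parse as
    :meth:`CellTypeCandidate.from_dict` (breakdown conservation is enforced
    on parse).  Anything else raises :class:`BackendError`.
    """

    def __init__(self, transport: Callable[[str], str], name: str = "completion", deterministic: bool = False):
        self._transport = transport
        self.name = name
        self.deterministic = deterministic

    @staticmethod
    def build_request(
        shortlist: CandidateShortlist,
        evidence: ClusterEvidence,
        context: BiologicalContext,
        config: RubricConfig,
    ) -> str:
        payload = {
            "cluster_id": shortlist.cluster_id,
            "shortlist": list(shortlist.names),
            "top_degs": list(evidence.degs),
            "significant_pathways": sorted(evidence.significant_terms(config.significance)),
            "pathways_available": evidence.enrichment is not None,
            "context": {
                "tissue": context.tissue,
                "condition": context.condition,
                "species": context.species,
            },
            "rubric": {
                "marker_match_max": config.marker_match_max,
                "narrow_marker_max": config.narrow_marker_max,
                "shared_marker_deduction": config.shared_marker_deduction,
                "negative_marker_deduction": config.negative_marker_deduction,
                "pathway_state_max": config.pathway_state_max,
                "pathway_type_max": config.pathway_type_max,
                "pathway_shared_deduction": config.pathway_shared_deduction,
                "pathway_conflict_deduction": config.pathway_conflict_deduction,
                "context_type_max": config.context_type_max,
                "context_state_max": config.context_state_max,
                "context_implausible_deduction": config.context_implausible_deduction,
            },
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @staticmethod
    def parse_response(text: str) -> list[CellTypeCandidate]:
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise BackendError(f"backend response is not valid JSON: {exc}") from exc
        if not isinstance(payload, dict) or set(payload) != {"candidates"}:
            raise BackendError("backend response must be exactly {'candidates': [...]}")
        if not isinstance(payload["candidates"], list):
            raise BackendError("'candidates' must be a list")
        return [CellTypeCandidate.from_dict(item) for item in payload["candidates"]]

    def score_shortlist(self, shortlist, evidence, context, kb, config):
        request = self.build_request(shortlist, evidence, context, config)
        response = self._transport(request)
        candidates = self.parse_response(response)
        candidates.sort(key=lambda c: (-c.total, c.name))
        return candidates


class ReplayTransport:
    """Answers completion requests from a recorded (hash → response) fixture.

    Recordings are JSON: ``{"records": {sha256(request): response, ...}}``.
    A request without a recording raises :class:`ReplayMissError` — the mock
    never improvises.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        data = json.loads(self.path.read_text())
        self.records: dict[str, str] = dict(data.get("records", {}))

    @staticmethod
    def request_key(request: str) -> str:
        return hashlib.sha256(request.encode()).hexdigest()

    @classmethod
    def record(cls, path: str | Path, pairs: Mapping[str, str]) -> None:
        """Write a recording mapping request text → response text."""
        records = {cls.request_key(req): resp for req, resp in pairs.items()}
        Path(path).write_text(json.dumps({"records": records}, indent=1, sort_keys=True))

    def __call__(self, request: str) -> str:
        key = self.request_key(request)
        if key not in self.records:
            raise ReplayMissError(f"no recorded response for request hash {key}")
        return self.records[key]


def make_backend(name: str) -> Backend:
    """Backend factory: ``rubric`` or ``replay:<fixture path>``."""
    if name == "rubric":
        return RubricBackend()
    if name.startswith("replay:"):
        transport = ReplayTransport(name.split(":", 1)[1])
        return CompletionBackend(transport, name="replay", deterministic=True)
    raise PipelineError(f"unknown backend {name!r}")


def prospect(
    context: BiologicalContext,
    kb: MarkerKnowledgeBase,
    limit: int = 10,
    cluster_id: str = "",
) -> CandidateShortlist:
    """Prospector stage: shortlist cell types plausible in the tissue context.

    With an empty tissue every KB entry is plausible.  If a declared tissue
    matches no entry at all the Prospector falls back to the whole KB rather
    than hand the Insightor an empty shortlist; each name carries a
    provenance note saying which rule admitted it.  Entries are ordered by
    name and truncated to ``limit``.
    """
    if len(kb) == 0:
        raise PipelineError("cannot prospect over an empty knowledge base")
    if limit <= 0:
        raise PipelineError("shortlist limit must be positive")
    tissue = normalize_label(context.tissue)
    if not tissue:
        picked = [(e.cell_type_name, "unrestricted context") for e in kb]
    else:
        picked = [
            (e.cell_type_name, f"plausible in tissue {context.tissue!r}")
            for e in kb
            if tissue in {normalize_label(t) for t in e.plausible_tissues}
        ]
        if not picked:
            logger.warning(
                "no KB entry is plausible in tissue %r; falling back to the full KB",
                context.tissue,
            )
            picked = [(e.cell_type_name, "fallback: no tissue-matched entries") for e in kb]
    picked.sort(key=lambda x: x[0])
    picked = picked[:limit]
    return CandidateShortlist(
        cluster_id=cluster_id,
        names=tuple(name for name, _ in picked),
        provenance={name: why for name, why in picked},
    )


def insight(
    shortlist: CandidateShortlist,
    evidence: ClusterEvidence,
    context: BiologicalContext,
    kb: MarkerKnowledgeBase,
    config: RubricConfig = DEFAULT_RUBRIC,
    backend: Optional[Backend] = None,
) -> list[CellTypeCandidate]:
    """Insightor stage: score every shortlisted candidate via the backend."""
    if not shortlist.names:
        raise PipelineError(f"empty shortlist for cluster {shortlist.cluster_id!r}")
    backend = backend or RubricBackend()
    return backend.score_shortlist(shortlist, evidence, context, kb, config)


@dataclass(frozen=True)
class ReviewedCluster:
    """Reviewer output for one cluster: three slots, flags, evidence summary."""

    cluster_id: str
    slots: tuple[Optional[CellTypeCandidate], ...]
    flags: tuple[str, ...] = ()
    top_degs: tuple[str, ...] = ()
    significant_pathways: tuple[str, ...] = ()
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.slots) != 3:
            raise PipelineError("a reviewed cluster carries exactly three candidate slots")


def review(
    candidates: Sequence[CellTypeCandidate],
    cluster_id: str,
    *,
    evidence: Optional[ClusterEvidence] = None,
    context: Optional[BiologicalContext] = None,
    kb: Optional[MarkerKnowledgeBase] = None,
    config: PipelineConfig = PipelineConfig(),
) -> ReviewedCluster:
    """Reviewer stage: rank, keep exactly three, tier confidence, flag ties.

    Candidates are sorted by total descending, name ascending.  When fewer
    than three arrive and a KB is available, the remaining KB entries are
    rubric-scored and used as lower-ranked padding; slots that still cannot
    be filled are explicitly absent (None).  The cluster is flagged
    ``low_agreement`` when the top two totals differ by less than the
    configured margin.
    """
    if not candidates and kb is None:
        raise PipelineError(f"review needs at least one scored candidate for {cluster_id!r}")
    ranked = sorted(candidates, key=lambda c: (-c.total, c.name))
    if len(ranked) < 3 and kb is not None and evidence is not None:
        have = {c.name for c in ranked}
        pad_names = [n for n in kb.names if n not in have]
        ctx = context or evidence.context
        pads = []
        shortlist_entries = [e for e in (kb.entry_for(n) for n in have) if e is not None]
        for name in pad_names:
            entry = kb.get(name)
            breakdown = score_candidate(evidence, entry, shortlist_entries, ctx, config.rubric)
            pads.append(_candidate_from_entry(entry, breakdown, evidence, ctx))
        pads.sort(key=lambda c: (-c.total, c.name))
        ranked += pads[: 3 - len(ranked)]
    slots = tuple(
        replace(c, confidence=config.tier(c.total)) for c in ranked[:3]
    ) + (None,) * max(0, 3 - len(ranked))
    flags: list[str] = []
    real = [s for s in slots if s is not None]
    if len(real) >= 2 and (real[0].total - real[1].total) < config.low_agreement_margin:
        flags.append("low_agreement")
    if evidence is not None and not evidence.degs:
        flags.append("no_deg_evidence")
    return ReviewedCluster(
        cluster_id=cluster_id,
        slots=slots[:3],
        flags=tuple(flags),
        top_degs=evidence.degs if evidence is not None else (),
        significant_pathways=tuple(sorted(evidence.significant_terms(config.rubric.significance)))
        if evidence is not None
        else (),
    )


def standardize(labels: Iterable[str], kb: MarkerKnowledgeBase) -> dict[str, str]:
    """Harmonize predicted labels to canonical KB names.

    Unresolvable labels are kept verbatim and logged — downstream consumers
    see a uniform naming for everything the KB knows about.
    """
    out: dict[str, str] = {}
    for label in labels:
        canonical = kb.resolve(label)
        if canonical is None:
            logger.warning("label %r does not resolve in the knowledge base; kept verbatim", label)
            out[label] = label
        else:
            out[label] = canonical
    return out


def _annotate_one(
    data: CountsWithClusters,
    cluster: str,
    kb: MarkerKnowledgeBase,
    collection: Optional[GeneSetCollection],
    context: BiologicalContext,
    config: PipelineConfig,
    backend: Backend,
) -> ReviewedCluster:
    try:
        markers = rank_markers(data, cluster, top_n=config.top_n)
        enrichment = None
        if collection is not None:
            enrichment = ora_enrich(markers.genes, collection, data.gene_names)
        evidence = ClusterEvidence(
            cluster_id=cluster, markers=markers, enrichment=enrichment, context=context
        )
        shortlist = prospect(context, kb, limit=config.shortlist_limit, cluster_id=cluster)
        candidates = insight(shortlist, evidence, context, kb, config.rubric, backend)
        return review(
            candidates, cluster, evidence=evidence, context=context, kb=kb, config=config
        )
    except Exception as exc:  # isolation: one bad cluster must not sink the run
        logger.error("cluster %s failed: %s", cluster, exc)
        return ReviewedCluster(
            cluster_id=cluster, slots=(None, None, None), flags=("error",), error=str(exc)
        )


def annotate_all(
    data: CountsWithClusters,
    kb: MarkerKnowledgeBase,
    collection: Optional[GeneSetCollection],
    context: BiologicalContext,
    config: PipelineConfig = PipelineConfig(),
    backend: Optional[Backend] = None,
):
    """Annotate every cluster and assemble the full report.

    Clusters are processed independently (optionally on ``config.n_jobs``
    threads); the report is assembled in cluster-id order, so the output is
    invariant to processing order.  Per-cluster failures are recorded in
    the report; only invalid global inputs abort the run.  Candidate names
    are standardized to canonical KB labels before assembly.
    """
    from .report import build_report  # deferred to avoid a module cycle

    if len(kb) == 0:
        raise PipelineError("knowledge base is empty")
    clusters = data.cluster_ids
    if len(clusters) < 2:
        raise PipelineError("differential expression needs at least 2 clusters")
    backend = backend or make_backend(config.backend)

    def worker(cluster: str) -> ReviewedCluster:
        return _annotate_one(data, cluster, kb, collection, context, config, backend)

    if config.n_jobs > 1:
        with ThreadPoolExecutor(max_workers=config.n_jobs) as pool:
            results = list(pool.map(worker, clusters))
    else:
        results = [worker(c) for c in clusters]

    # uniform naming across clusters
    labels = {s.name for r in results for s in r.slots if s is not None}
    mapping = standardize(labels, kb)
    results = [
        replace(
            r,
            slots=tuple(
                None if s is None else replace(s, name=mapping.get(s.name, s.name))
                for s in r.slots
            ),
        )
        for r in results
    ]
    results.sort(key=lambda r: r.cluster_id)
    return build_report(results, config=config, backend_name=backend.name)
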