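"""Three-level ontology agreement metric and benchmark aggregation.

Two annotations agree fully (1.0) when they resolve to the same canonical
label or the same Cell Ontology term; partially (0.5) when one term is an
is_a ancestor of the other at any distance, or both map to the same
configured broad category; and not at all (0.0) otherwise.  Because a
cluster carries three ranked candidates, its agreement with the reference is
the maximum over the candidates, and a benchmark is summarized by the mean
of the per-cluster maxima.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .knowledge import MarkerKnowledgeBase, OntologyGraph, normalize_label

logger = logging.getLogger("cellscribe")

FULL, PARTIAL, MISMATCH = 1.0, 0.5, 0.0


def _resolve(label: str, kb: Optional[MarkerKnowledgeBase], ontology: Optional[OntologyGraph]):
    """(canonical comparison string, CL term id or None) for a free-text label."""
    canonical, cl_id = normalize_label(label), None
    if kb is not None:
        entry = kb.entry_for(label)
        if entry is not None:
            canonical, cl_id = normalize_label(entry.cell_type_name), entry.cl_id
    if cl_id is None and ontology is not None:
        cl_id = ontology.id_for_name(label) or (label if label in ontology else None)
    return canonical, cl_id


def agreement(
    predicted: str,
    reference: str,
    kb: Optional[MarkerKnowledgeBase] = None,
    ontology: Optional[OntologyGraph] = None,
) -> float:
    """Three-level agreement between a predicted and a reference label.

    Symmetric in its arguments.  Labels that resolve neither in the KB nor in
    the ontology are compared by normalized string only (logged): ontology
    levels cannot apply without a term.
    """
    if not predicted.strip() or not reference.strip():
        raise ValueError("agreement requires nonempty labels")
    pred_name, pred_id = _resolve(predicted, kb, ontology)
    ref_name, ref_id = _resolve(reference, kb, ontology)
    if pred_id is None or ref_id is None:
        logger.info(
            "label without CL resolution (%r vs %r); string comparison only", predicted, reference
        )
    if pred_name == ref_name:
        return FULL
    if pred_id is not None and pred_id == ref_id:
        return FULL
    if ontology is not None and pred_id is not None and ref_id is not None:
        if ontology.related_by_lineage(pred_id, ref_id):
            return PARTIAL
        if ontology.same_broad_category(pred_id, ref_id):
            return PARTIAL
    return MISMATCH


@dataclass(frozen=True)
class AgreementResult:
    """Per-cluster agreement: candidate-wise levels and their maximum."""

    cluster_id: str
    per_candidate: tuple[float, ...]
    score: float
    matched_candidate: Optional[int]

    def __post_init__(self) -> None:
        if self.per_candidate and self.score != max(self.per_candidate):
            raise ValueError("cluster score must be the max over candidates")


def cluster_agreement(
    candidates: Sequence[str],
    reference: str,
    kb: Optional[MarkerKnowledgeBase] = None,
    ontology: Optional[OntologyGraph] = None,
    cluster_id: str = "",
) -> AgreementResult:
    """Max-over-candidates agreement for one cluster's ranked candidates."""
    if not candidates:
        raise ValueError("cluster_agreement needs at least one candidate")
    scores = tuple(agreement(c, reference, kb, ontology) for c in candidates)
    best = max(scores)
    return AgreementResult(
        cluster_id=cluster_id,
        per_candidate=scores,
        score=best,
        matched_candidate=scores.index(best),
    )


@dataclass(frozen=True)
class BenchmarkSummary:
    """Benchmark aggregate: mean agreement and per-level counts."""

    results: tuple[AgreementResult, ...]
    mean_agreement: float
    n_full: int
    n_partial: int
    n_mismatch: int

    def to_dict(self) -> dict:
        return {
            "mean_agreement": self.mean_agreement,
            "n_clusters": len(self.results),
            "n_full": self.n_full,
            "n_partial": self.n_partial,
            "n_mismatch": self.n_mismatch,
            "clusters": {
                r.cluster_id: {"score": r.score, "per_candidate": list(r.per_candidate)}
                for r in self.results
            },
        }


def summarize(results: Sequence[AgreementResult]) -> BenchmarkSummary:
    """Mean of per-cluster scores plus full/partial/mismatch tallies."""
    if not results:
        raise ValueError("cannot summarize zero agreement results")
    scores = [r.score for r in results]
    return BenchmarkSummary(
        results=tuple(results),
        mean_agreement=sum(scores) / len(scores),
        n_full=sum(s == FULL for s in scores),
        n_partial=sum(s == PARTIAL for s in scores),
        n_mismatch=sum(s == MISMATCH for s in scores),
    )


def load_reference_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (cluster_id, reference_label); '#' comments tolerated."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if list(table.iloc[0]) == ["cluster_id", "reference_label"]:
        table = table.iloc[1:]
    return dict(zip(table[0], table[1]))


def evaluate_report(
    report,
    reference: dict[str, str],
    kb: Optional[MarkerKnowledgeBase] = None,
    ontology: Optional[OntologyGraph] = None,
) -> BenchmarkSummary:
    """Score an annotation report against reference labels, cluster by cluster.

    Clusters without a reference label or without any candidate are skipped
    with a log message.
    """
    results = []
    for cluster in report.clusters:
        ref = reference.get(cluster.cluster_id)
        if ref is None:
            logger.warning("no reference label for cluster %s; skipped", cluster.cluster_id)
            continue
        names = cluster.candidate_names()
        if not names:
            logger.warning("cluster %s has no candidates; skipped", cluster.cluster_id)
            continue
        results.append(cluster_agreement(names, ref, kb, ontology, cluster_id=cluster.cluster_id))
    return summarize(results)


def write_summary(summary: BenchmarkSummary, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "agreement.json").write_text(json.dumps(summary.to_dict(), indent=1) + "\n")
    pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "score": r.score,
                "matched_candidate": r.matched_candidate,
            }
            for r in summary.results
        ]
    ).to_csv(out_dir / "agreement.tsv", sep="\t", index=False)
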