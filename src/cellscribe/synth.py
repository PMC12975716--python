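"""Seeded synthetic clustered count matrices with planted marker signatures.

Each knowledge-base entry becomes one cluster.  Counts are negative binomial
with a common baseline mean; within a cluster, the planted type's positive
markers have their mean multiplied by ``marker_fold`` and its negative
markers suppressed by ``negative_suppression``, so a correct annotator
should recover each planted identity from the differential-expression
signal alone.  Library-size variation, dropout, batch effects and doublets
are deliberately not modeled — the generator exercises the statistics, not
the messiness, of real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .evidence import CountsWithClusters
from .knowledge import MarkerEntry, MarkerKnowledgeBase

logger = logging.getLogger("cellscribe")


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    ``baseline_mean`` and ``dispersion`` parameterize the negative binomial
    as (mean m, size r) with variance m + m²/r; ``marker_fold`` (> 1)
    multiplies a planted marker's mean in its own cluster.
    """

    kb: MarkerKnowledgeBase
    cells_per_cluster: int = 50
    n_background_genes: int = 200
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    marker_fold: float = 8.0
    negative_suppression: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_cluster < 2:
            raise ValueError("cells_per_cluster must be ≥ 2")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be ≥ 0")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1 (planted signal must be real)")
        if not (0 < self.negative_suppression < 1):
            raise ValueError("negative_suppression must lie in (0, 1)")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # numpy's NB is (n, p) with mean n(1-p)/p; mean m, size r → p = r/(r+m)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate(spec: SynthSpec) -> tuple[CountsWithClusters, dict[str, str]]:
    """Simulate one cluster per KB entry; returns data + ground-truth map.

    Gene list = union of all KB markers (sorted) + background genes named
    GBG0001… (names chosen to avoid collision with real symbols).  Marker
    overlap between planted types is allowed (it exercises the shared-marker
    deduction) and logged.
    """
    entries = list(spec.kb)
    if not entries:
        raise ValueError("synthetic generation needs a nonempty knowledge base")
    for entry in entries:
        if not entry.broad_markers:
            raise ValueError(f"entry {entry.cell_type_name!r} has no broad markers to plant")
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            overlap = a.positive_markers & b.positive_markers
            if overlap:
                logger.info(
                    "planted types %r and %r share markers %s",
                    a.cell_type_name,
                    b.cell_type_name,
                    sorted(overlap),
                )

    marker_genes = sorted({g for e in entries for g in e.positive_markers | e.negative_markers})
    background = [f"GBG{i + 1:04d}" for i in range(spec.n_background_genes)]
    genes = marker_genes + background
    gene_index = {g: j for j, g in enumerate(genes)}

    rng = np.random.default_rng(spec.seed)
    n_clusters = len(entries)
    n_cells = n_clusters * spec.cells_per_cluster
    means = np.full((n_cells, len(genes)), spec.baseline_mean)
    cluster_of: list[str] = []
    truth: dict[str, str] = {}
    for ci, entry in enumerate(entries):
        cluster_id = f"c{ci}"
        truth[cluster_id] = entry.cell_type_name
        rows = slice(ci * spec.cells_per_cluster, (ci + 1) * spec.cells_per_cluster)
        for g in entry.positive_markers:
            means[rows, gene_index[g]] *= spec.marker_fold
        for g in entry.negative_markers:
            means[rows, gene_index[g]] *= spec.negative_suppression
        cluster_of += [cluster_id] * spec.cells_per_cluster

    counts = _nb_draw(rng, means, spec.dispersion)
    data = CountsWithClusters(
        counts=counts,
        gene_names=tuple(genes),
        cell_names=tuple(f"cell{i:05d}" for i in range(n_cells)),
        cluster_of=tuple(cluster_of),
    )
    return data, truth


def make_reference_labels(truth: dict[str, str], path: Optional[str | Path] = None) -> pd.DataFrame:
    """Ground truth as the evaluation module's reference-label table."""
    table = pd.DataFrame(
        sorted(truth.items()), columns=["cluster_id", "reference_label"]
    )
    if path is not None:
        table.to_csv(path, sep="\t", index=False, header=False)
    return table


def write_fixture(data: CountsWithClusters, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit counts.csv + clusters.tsv matching the evidence readers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_path = out_dir / "counts.csv"
    clusters_path = out_dir / "clusters.tsv"
    pd.DataFrame(data.counts, index=list(data.cell_names), columns=list(data.gene_names)).to_csv(
        counts_path
    )
    pd.DataFrame({"cell": data.cell_names, "cluster": data.cluster_of}).to_csv(
        clusters_path, sep="\t", index=False, header=False
    )
    return counts_path, clusters_path


def demo_knowledge_base() -> MarkerKnowledgeBase:
    """Five blood cell types with distinct canonical markers.

    This is the default simulation KB: real immunology marker symbols,
    distinct across types so planted-signature recovery is well posed, with
    negative markers crossing types (a B-cell cluster should not express
    CD3D, and so on).
    """
    return MarkerKnowledgeBase(
        [
            MarkerEntry(
                cell_type_name="B cell",
                cl_id="CL:0000236",
                broad_markers={"CD19", "MS4A1", "CD79A"},
                narrow_markers={"CD79B", "TCL1A"},
                negative_markers={"CD3D", "NKG7"},
                plausible_tissues={"blood", "lymph node", "spleen"},
                plausible_states={"naive", "memory@blood"},
                pathways_type={"B cell receptor signaling"},
                pathways_state={"antigen presentation"},
                synonyms={"B cells", "B-cell", "B lymphocyte"},
            ),
            MarkerEntry(
                cell_type_name="T cell",
                cl_id="CL:0000084",
                broad_markers={"CD3D", "CD3E", "CD2"},
                narrow_markers={"IL7R", "TRAC"},
                negative_markers={"CD19", "CD14"},
                plausible_tissues={"blood", "lymph node", "thymus"},
                plausible_states={"naive", "activated@blood/inflammation"},
                pathways_type={"T cell receptor signaling"},
                pathways_state={"interferon response"},
                synonyms={"T cells", "T-cell", "T lymphocyte"},
            ),
            MarkerEntry(
                cell_type_name="natural killer cell",
                cl_id="CL:0000623",
                broad_markers={"NKG7", "GNLY", "KLRD1"},
                narrow_markers={"PRF1", "KLRF1"},
                negative_markers={"CD3D", "CD79A"},
                plausible_tissues={"blood", "spleen"},
                plausible_states={"cytotoxic"},
                pathways_type={"natural killer cell cytotoxicity"},
                pathways_state={"interferon response"},
                synonyms={"NK cell", "NK cells"},
            ),
            MarkerEntry(
                cell_type_name="monocyte",
                cl_id="CL:0000576",
                broad_markers={"CD14", "LYZ", "FCN1"},
                narrow_markers={"S100A8", "S100A9"},
                negative_markers={"CD3D", "MS4A1"},
                plausible_tissues={"blood", "bone marrow"},
                plausible_states={"classical", "inflammatory@blood/inflammation"},
                pathways_type={"phagocytosis"},
                pathways_state={"inflammatory response"},
                synonyms={"monocytes", "classical monocyte"},
            ),
            MarkerEntry(
                cell_type_name="dendritic cell",
                cl_id="CL:0000451",
                broad_markers={"FCER1A", "CST3", "CLEC10A"},
                narrow_markers={"CD1C", "ITGAX"},
                negative_markers={"CD3D", "NKG7"},
                plausible_tissues={"blood", "lymph node", "skin"},
                plausible_states={"conventional"},
                pathways_type={"antigen processing and presentation"},
                pathways_state={"antigen presentation"},
                synonyms={"dendritic cells", "DC"},
            ),
        ]
    )
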