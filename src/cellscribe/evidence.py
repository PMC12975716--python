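"""Per-cluster evidence: ranked marker genes and pathway over-representation.

Differential expression is one-vs-rest Wilcoxon rank-sum (Mann-Whitney U) per
gene on log1p CP10K-normalized counts, with Benjamini-Hochberg adjustment
across genes.  Pathway evidence is a hypergeometric over-representation test
of the cluster's top markers against a GMT gene-set collection, BH-adjusted
across terms.  Every ranking ends in lexicographic gene/term order so that
the whole pipeline is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import log2
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .knowledge import BiologicalContext, normalize_gene

logger = logging.getLogger("cellscribe")

#: default number of top DEGs carried into shortlist scoring
DEFAULT_TOP_N = 20
#: BH-adjusted significance cut for enrichment terms used downstream
DEFAULT_SIGNIFICANCE = 0.05


class EvidenceError(ValueError):
    """Invalid evidence input (degenerate clusters, empty query/universe...)."""


@dataclass(frozen=True)
class CountsWithClusters:
    """Cells × genes raw count matrix with per-cell cluster assignments."""

    counts: np.ndarray
    gene_names: tuple[str, ...]
    cell_names: tuple[str, ...]
    cluster_of: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise EvidenceError("counts must be a 2-D cells × genes matrix")
        if np.any(counts < 0):
            raise EvidenceError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_names", tuple(normalize_gene(g) for g in self.gene_names))
        object.__setattr__(self, "cell_names", tuple(self.cell_names))
        object.__setattr__(self, "cluster_of", tuple(str(c) for c in self.cluster_of))
        n_cells, n_genes = counts.shape
        if len(self.gene_names) != n_genes:
            raise EvidenceError(f"{len(self.gene_names)} gene names for {n_genes} columns")
        if len(self.cell_names) != n_cells or len(self.cluster_of) != n_cells:
            raise EvidenceError("cell_names and cluster_of must match the matrix rows")
        if len(set(self.gene_names)) != n_genes:
            raise EvidenceError("gene names must be unique")

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(set(self.cluster_of))

    def cells_in(self, cluster: str) -> np.ndarray:
        return np.asarray([c == cluster for c in self.cluster_of])

    @classmethod
    def from_anndata(cls, adata, cluster_key: str) -> "CountsWithClusters":
        """Build from an AnnData object; ``obs[cluster_key]`` holds clusters."""
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(
            counts=np.asarray(X),
            gene_names=tuple(adata.var_names),
            cell_names=tuple(adata.obs_names),
            cluster_of=tuple(str(c) for c in adata.obs[cluster_key]),
        )


def load_counts(
    counts_path: str | Path,
    clusters_path: Optional[str | Path] = None,
    cluster_key: str = "cluster",
) -> CountsWithClusters:
    """Read counts from h5ad, or from a dense CSV matrix + cell/cluster TSV.

    CSV: first column cell names, header row gene symbols.  Cluster TSV: two
    columns (cell, cluster), optional header, ``#`` comments tolerated.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".h5ad":
        import anndata as ad

        return CountsWithClusters.from_anndata(ad.read_h5ad(counts_path), cluster_key)
    if clusters_path is None:
        raise EvidenceError("CSV counts require a cluster-assignment TSV")
    matrix = pd.read_csv(counts_path, index_col=0)
    labels = pd.read_csv(clusters_path, sep="\t", header=None, comment="#", dtype=str)
    if list(labels.iloc[0]) == ["cell", "cluster"]:
        labels = labels.iloc[1:]
    cluster_map = dict(zip(labels[0], labels[1]))
    missing = [c for c in matrix.index if str(c) not in cluster_map]
    if missing:
        raise EvidenceError(f"cells without a cluster assignment: {missing[:5]}")
    return CountsWithClusters(
        counts=matrix.to_numpy(),
        gene_names=tuple(matrix.columns),
        cell_names=tuple(str(c) for c in matrix.index),
        cluster_of=tuple(cluster_map[str(c)] for c in matrix.index),
    )


@dataclass(frozen=True)
class RankedMarkers:
    """Top DEGs for one cluster, ranked by (adjusted p ↑, log2FC ↓, symbol ↑)."""

    cluster_id: str
    table: pd.DataFrame  # columns: gene, log2_fold_change, p_value, adjusted_p, rank

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.table["gene"])

    @classmethod
    def from_genes(cls, cluster_id: str, genes: Sequence[str]) -> "RankedMarkers":
        """Minimal ranked list from bare symbols (for constructed evidence)."""
        genes = [normalize_gene(g) for g in genes]
        return cls(
            cluster_id=cluster_id,
            table=pd.DataFrame(
                {
                    "gene": genes,
                    "log2_fold_change": np.nan,
                    "p_value": np.nan,
                    "adjusted_p": np.nan,
                    "rank": np.arange(1, len(genes) + 1),
                }
            ),
        )


def rank_markers(data: CountsWithClusters, cluster: str, top_n: int = DEFAULT_TOP_N) -> RankedMarkers:
    """One-vs-rest Wilcoxon rank-sum DE for one cluster.

    DEGs here are genes *over-expressed* in the cluster, so the test is
    one-sided: p-values come from ``scipy.stats.mannwhitneyu`` with
    ``alternative="greater"`` (exact when both groups are ≤8 cells and
    untied, normal approximation otherwise), BH-adjusted across genes.
    Genes whose values are constant across all cells get p = 1 and
    log2FC = 0.  log2FC compares mean CP10K expression with a pseudocount
    of 1.
    """
    if top_n <= 0:
        raise EvidenceError("top_n must be positive")
    mask = data.cells_in(cluster)
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 2 or n_out < 2:
        raise EvidenceError(
            f"cluster {cluster!r} needs ≥2 cells on each side of the comparison "
            f"(got {n_in} vs {n_out})"
        )
    lib = data.counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    norm = data.counts / lib * 1e4
    log_norm = np.log1p(norm)
    x, y = log_norm[mask], log_norm[~mask]

    constant = np.ptp(log_norm, axis=0) == 0
    pvals = np.ones(log_norm.shape[1])
    if (~constant).any():
        res = stats.mannwhitneyu(x[:, ~constant], y[:, ~constant], alternative="greater", axis=0)
        pvals[~constant] = np.minimum(res.pvalue, 1.0)
    lfc = np.where(
        constant, 0.0, np.log2((norm[mask].mean(axis=0) + 1.0) / (norm[~mask].mean(axis=0) + 1.0))
    )
    adjusted = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": data.gene_names,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": adjusted,
        }
    )
    # signed (not absolute) fold-change tie-break: the list holds genes
    # over-expressed in the cluster, so down-regulated genes must sort last
    table = table.sort_values(
        by=["adjusted_p", "log2_fold_change", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    if top_n > len(table):
        logger.warning(
            "top_n=%d exceeds gene count %d for cluster %s; truncating", top_n, len(table), cluster
        )
        top_n = len(table)
    table = table.head(top_n).copy()
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedMarkers(cluster_id=cluster, table=table)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets, typically read from a GMT file."""

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            genes = frozenset(normalize_gene(g) for g in genes)
            if not name.strip():
                raise EvidenceError("gene-set names must be nonempty")
            if not genes:
                raise EvidenceError(f"gene set {name!r} is empty")
            if name in clean:
                raise EvidenceError(f"duplicate gene-set name {name!r}")
            clean[name] = genes
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """GMT: one set per line — name<TAB>description<TAB>gene1<TAB>gene2..."""
        sets: dict[str, frozenset[str]] = {}
        for raw in Path(path).read_text().splitlines():
            if not raw.strip() or raw.startswith("#"):
                continue
            cells = raw.rstrip("\n").split("\t")
            if len(cells) < 3:
                raise EvidenceError(f"malformed GMT line: {raw[:60]!r}")
            if cells[0] in sets:
                raise EvidenceError(f"duplicate gene-set name {cells[0]!r}")
            sets[cells[0]] = frozenset(g for g in cells[2:] if g.strip())
        return cls(sets=sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set in the query."""

    term: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if self.overlap_count > min(self.set_size, self.query_size):
            raise EvidenceError(f"term {self.term!r}: overlap exceeds set/query size")
        if not (0 < self.p_value <= 1):
            raise EvidenceError(f"term {self.term!r}: p-value {self.p_value} outside (0, 1]")


def ora_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``query`` against each set in ``collection``.

    p = P(X ≥ overlap) with X ~ Hypergeometric(universe, set∩universe,
    |query|); BH adjustment across tested terms; results sorted by
    (adjusted p, term name).  Sets with no genes in the universe are skipped.
    """
    query_set = frozenset(normalize_gene(g) for g in query)
    universe_set = frozenset(normalize_gene(g) for g in universe)
    if not query_set:
        raise EvidenceError("empty ORA query")
    if not universe_set:
        raise EvidenceError("empty ORA universe")
    if not query_set <= universe_set:
        raise EvidenceError(f"query genes outside the universe: {sorted(query_set - universe_set)[:5]}")

    N, n = len(universe_set), len(query_set)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & universe_set
        if not members:
            logger.info("ORA term %r has no genes in the universe; skipped", term)
            continue
        K = len(members)
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    if not rows:
        return []
    adjusted = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term=term,
            overlap_count=k,
            set_size=K,
            query_size=n,
            universe_size=N,
            p_value=p,
            adjusted_p=float(adj),
        )
        for (term, k, K, p), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term))
    return results


@dataclass(frozen=True)
class ClusterEvidence:
    """All data-driven evidence for one cluster: DEGs, enrichment, context.

    ``enrichment`` is None when no gene-set collection was supplied — this is
    what switches downstream scoring onto the two-component (marker+context)
    rubric — and a possibly-empty list otherwise.
    """

    cluster_id: str
    markers: RankedMarkers
    enrichment: Optional[list[EnrichmentResult]]
    context: BiologicalContext = field(default_factory=BiologicalContext)

    @property
    def degs(self) -> tuple[str, ...]:
        return self.markers.genes

    def significant_terms(self, alpha: float = DEFAULT_SIGNIFICANCE) -> frozenset[str]:
        if not self.enrichment:
            return frozenset()
        return frozenset(r.term for r in self.enrichment if r.adjusted_p < alpha)

    @classmethod
    def from_genes(
        cls,
        cluster_id: str,
        genes: Sequence[str],
        enrichment: Optional[list[EnrichmentResult]] = None,
        context: Optional[BiologicalContext] = None,
    ) -> "ClusterEvidence":
        """Constructed evidence from bare gene symbols (tests, what-if audits)."""
        return cls(
            cluster_id=cluster_id,
            markers=RankedMarkers.from_genes(cluster_id, genes),
            enrichment=enrichment,
            context=context or BiologicalContext(),
        )


def significant_enrichment(
    term: str,
    *,
    adjusted_p: float = 1e-6,
    overlap: int = 5,
    set_size: int = 10,
    query_size: int = 20,
    universe_size: int = 1000,
) -> EnrichmentResult:
    """Hand-built significant enrichment row (fixture helper for audits/tests)."""
    return EnrichmentResult(
        term=term,
        overlap_count=overlap,
        set_size=set_size,
        query_size=query_size,
        universe_size=universe_size,
        p_value=adjusted_p,
        adjusted_p=adjusted_p,
    )


def extract_evidence(
    data: CountsWithClusters,
    collection: Optional[GeneSetCollection],
    context: BiologicalContext,
    top_n: int = DEFAULT_TOP_N,
) -> dict[str, ClusterEvidence]:
    """Bundle ranked markers + ORA + context for every cluster.

    The ORA universe is all genes in the matrix; the query is the cluster's
    top ``top_n`` DEGs.  With ``collection=None`` the enrichment stream is
    absent (two-component scoring downstream).
    """
    out: dict[str, ClusterEvidence] = {}
    for cluster in data.cluster_ids:
        markers = rank_markers(data, cluster, top_n=top_n)
        enrichment = None
        if collection is not None:
            enrichment = ora_enrich(markers.genes, collection, data.gene_names)
        out[cluster] = ClusterEvidence(
            cluster_id=cluster, markers=markers, enrichment=enrichment, context=context
        )
    return out


def write_evidence_tables(evidence: Mapping[str, ClusterEvidence], out_dir: str | Path) -> None:
    """Per-cluster TSVs of ranked markers and enrichment results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cluster_id, ev in sorted(evidence.items()):
        ev.markers.table.to_csv(out_dir / f"markers_{cluster_id}.tsv", sep="\t", index=False)
        if ev.enrichment is not None:
            pd.DataFrame([r.__dict__ for r in ev.enrichment]).to_csv(
                out_dir / f"enrichment_{cluster_id}.tsv", sep="\t", index=False
            )
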