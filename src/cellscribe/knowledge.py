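"""Marker knowledge base, biological context, and cell-ontology graph.

The knowledge base is the prior the whole pipeline reasons against: for each
cell type it records canonical (broad) markers, high-specificity (narrow)
markers, negative markers that should *not* be expressed, the tissues and
states in which the type is plausible, and its characteristic pathway terms.
Entries may carry a Cell Ontology (CL) identifier so that annotations can be
compared at the ontology level rather than by string equality.

File dialects
-------------
KB TSV: fixed header
    cell_type, cl_id, broad_markers, narrow_markers, negative_markers,
    tissues, states, pathways_type, pathways_state, synonyms
with list cells delimited by ``|``; comment lines start with ``#``.
KB JSON mirrors the same fields as a list of objects.

Ontology: either OBO (parsed with obonet, ``is_a`` edges only) or a
child/parent edge TSV where a row ``child<TAB>parent`` declares an is_a edge
and a row with an empty second column declares an isolated term.  A term is
declared when it appears in the first column of some row; an edge whose
parent is never declared is an error.

State tags
----------
A plausible-state item is ``state``, ``state@tissue`` or
``state@tissue/condition``; an unset tag matches any context value.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

logger = logging.getLogger("cellscribe")

_WS = re.compile(r"\s+")

KB_TSV_HEADER = [
    "cell_type",
    "cl_id",
    "broad_markers",
    "narrow_markers",
    "negative_markers",
    "tissues",
    "states",
    "pathways_type",
    "pathways_state",
    "synonyms",
]


def normalize_label(label: str) -> str:
    """Lower-case, map ``-``/``_`` to space, collapse whitespace.

    This is the canonical comparison form for cell-type names, synonyms and
    tissue labels; case and hyphenation variants ("B-cell", "b cells") are the
    dominant failure mode when matching free-text labels.
    """
    return _WS.sub(" ", label.lower().replace("-", " ").replace("_", " ")).strip()


def normalize_gene(symbol: str) -> str:
    return symbol.strip().upper()


class KnowledgeBaseError(ValueError):
    """Invalid knowledge-base content (duplicates, marker conflicts, ...)."""


@dataclass(frozen=True)
class MarkerEntry:
    """Priors for one cell type: markers, plausibility, pathways, synonyms."""

    cell_type_name: str
    cl_id: Optional[str] = None
    broad_markers: frozenset[str] = frozenset()
    narrow_markers: frozenset[str] = frozenset()
    negative_markers: frozenset[str] = frozenset()
    plausible_tissues: frozenset[str] = frozenset()
    plausible_states: frozenset[str] = frozenset()
    pathways_type: frozenset[str] = frozenset()
    pathways_state: frozenset[str] = frozenset()
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cell_type_name.strip():
            raise KnowledgeBaseError("cell_type_name must be nonempty")
        for attr in ("broad_markers", "narrow_markers", "negative_markers"):
            object.__setattr__(self, attr, frozenset(normalize_gene(g) for g in getattr(self, attr) if g.strip()))
        for attr in ("plausible_tissues", "plausible_states", "pathways_type", "pathways_state", "synonyms"):
            object.__setattr__(self, attr, frozenset(s.strip() for s in getattr(self, attr) if s.strip()))
        overlap = (self.broad_markers | self.narrow_markers) & self.negative_markers
        if overlap:
            raise KnowledgeBaseError(
                f"entry {self.cell_type_name!r}: markers listed as both positive and "
                f"negative: {sorted(overlap)}"
            )
        if self.broad_markers & self.narrow_markers:
            raise KnowledgeBaseError(
                f"entry {self.cell_type_name!r}: markers listed as both broad and "
                f"narrow: {sorted(self.broad_markers & self.narrow_markers)}"
            )

    @property
    def positive_markers(self) -> frozenset[str]:
        return self.broad_markers | self.narrow_markers

    @property
    def characteristic_pathways(self) -> frozenset[str]:
        return self.pathways_type | self.pathways_state

    def plausible_state_for(self, tissue: str, condition: str) -> Optional[str]:
        """First (lexicographic) declared state compatible with the context.

        A state item ``name[@tissue[/condition]]`` is compatible when each
        set tag equals the corresponding context value (after label
        normalization).  Untagged states are compatible with any context.
        Returns None when no state fits or the entry declares none.
        """
        tissue_n = normalize_label(tissue)
        condition_n = normalize_label(condition)
        hits = []
        for item in self.plausible_states:
            name, tag_tissue, tag_condition = _parse_state(item)
            if tag_tissue and normalize_label(tag_tissue) != tissue_n:
                continue
            if tag_condition and normalize_label(tag_condition) != condition_n:
                continue
            hits.append(name)
        return min(hits) if hits else None

    def to_record(self) -> dict:
        return {
            "cell_type": self.cell_type_name,
            "cl_id": self.cl_id or "",
            "broad_markers": sorted(self.broad_markers),
            "narrow_markers": sorted(self.narrow_markers),
            "negative_markers": sorted(self.negative_markers),
            "tissues": sorted(self.plausible_tissues),
            "states": sorted(self.plausible_states),
            "pathways_type": sorted(self.pathways_type),
            "pathways_state": sorted(self.pathways_state),
            "synonyms": sorted(self.synonyms),
        }


def _parse_state(item: str) -> tuple[str, str, str]:
    name, _, tags = item.partition("@")
    tissue, _, condition = tags.partition("/")
    return name.strip(), tissue.strip(), condition.strip()


@dataclass(frozen=True)
class BiologicalContext:
    """Experimental context steering plausibility: tissue, condition, species.

    An empty tissue means "unrestricted": every cell type is then considered
    plausible and no implausibility deduction can fire.
    """

    tissue: str = ""
    condition: str = ""
    species: str = ""
    notes: str = ""

    @property
    def is_empty(self) -> bool:
        return not (self.tissue.strip() or self.condition.strip())


class MarkerKnowledgeBase:
    """Collection of :class:`MarkerEntry` keyed by canonical name.

    Lookup by any synonym (case/hyphen-insensitive) resolves to exactly one
    entry; a synonym colliding across entries is rejected at construction.
    """

    def __init__(self, entries: Iterable[MarkerEntry] = ()) -> None:
        self._entries: dict[str, MarkerEntry] = {}
        self._index: dict[str, str] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: MarkerEntry) -> None:
        if entry.cell_type_name in self._entries:
            raise KnowledgeBaseError(f"duplicate canonical name: {entry.cell_type_name!r}")
        keys = {normalize_label(entry.cell_type_name)}
        keys.update(normalize_label(s) for s in entry.synonyms)
        for key in keys:
            owner = self._index.get(key)
            if owner is not None and owner != entry.cell_type_name:
                raise KnowledgeBaseError(
                    f"label {key!r} collides between entries {owner!r} and "
                    f"{entry.cell_type_name!r}"
                )
        self._entries[entry.cell_type_name] = entry
        for key in keys:
            self._index[key] = entry.cell_type_name

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[MarkerEntry]:
        for name in sorted(self._entries):
            yield self._entries[name]

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) is not None

    @property
    def names(self) -> list[str]:
        return sorted(self._entries)

    def get(self, canonical_name: str) -> MarkerEntry:
        return self._entries[canonical_name]

    def resolve(self, label: str) -> Optional[str]:
        """Canonical name for ``label`` (name or synonym), or None."""
        return self._index.get(normalize_label(label))

    def entry_for(self, label: str) -> Optional[MarkerEntry]:
        name = self.resolve(label)
        return self._entries[name] if name is not None else None

    def save(self, path: str | Path, format: Optional[str] = None) -> None:
        path = Path(path)
        fmt = format or ("json" if path.suffix == ".json" else "tsv")
        records = [e.to_record() for e in self]
        if fmt == "json":
            path.write_text(json.dumps(records, indent=1) + "\n")
        elif fmt == "tsv":
            lines = ["\t".join(KB_TSV_HEADER)]
            for rec in records:
                lines.append(
                    "\t".join(
                        rec[col] if isinstance(rec[col], str) else "|".join(rec[col])
                        for col in KB_TSV_HEADER
                    )
                )
            path.write_text("\n".join(lines) + "\n")
        else:
            raise ValueError(f"unknown KB format: {fmt!r}")


def _split_list(cell: str) -> list[str]:
    return [item.strip() for item in cell.split("|") if item.strip()]


def _entry_from_record(rec: Mapping[str, object]) -> MarkerEntry:
    def as_list(value: object) -> list[str]:
        if isinstance(value, str):
            return _split_list(value)
        return [str(v) for v in value]  # type: ignore[union-attr]

    cl_id = str(rec.get("cl_id") or "").strip() or None
    return MarkerEntry(
        cell_type_name=str(rec["cell_type"]).strip(),
        cl_id=cl_id,
        broad_markers=frozenset(as_list(rec.get("broad_markers", []))),
        narrow_markers=frozenset(as_list(rec.get("narrow_markers", []))),
        negative_markers=frozenset(as_list(rec.get("negative_markers", []))),
        plausible_tissues=frozenset(as_list(rec.get("tissues", []))),
        plausible_states=frozenset(as_list(rec.get("states", []))),
        pathways_type=frozenset(as_list(rec.get("pathways_type", []))),
        pathways_state=frozenset(as_list(rec.get("pathways_state", []))),
        synonyms=frozenset(as_list(rec.get("synonyms", []))),
    )


def load_knowledge_base(path: str | Path, format: Optional[str] = None) -> MarkerKnowledgeBase:
    """Read a marker KB from TSV (fixed header) or JSON (list of objects)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "json":
        records = json.loads(path.read_text() or "[]")
    elif fmt == "tsv":
        records = []
        header: Optional[list[str]] = None
        for raw in path.read_text().splitlines():
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            cells = raw.rstrip("\n").split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = set(KB_TSV_HEADER) - set(header)
                if missing:
                    raise KnowledgeBaseError(f"KB TSV missing columns: {sorted(missing)}")
                continue
            cells += [""] * (len(header) - len(cells))
            records.append(dict(zip(header, cells)))
    else:
        raise ValueError(f"unknown KB format: {fmt!r}")
    if not records:
        logger.warning("knowledge base %s is empty", path)
    return MarkerKnowledgeBase(_entry_from_record(rec) for rec in records)


def resolve_label(label: str, kb: MarkerKnowledgeBase) -> Optional[str]:
    """Canonicalize a free-text cell-type label against the KB.

    Case-insensitive, whitespace/hyphen-normalized matching against canonical
    names and synonyms.  No-match is returned as None, not raised.
    """
    return kb.resolve(label)


class OntologyError(ValueError):
    """Invalid ontology input (cycles, undeclared edge endpoints)."""


@dataclass
class OntologyGraph:
    """Cell-ontology is_a DAG supporting ancestor queries.

    ``graph`` holds child→parent edges, so the ancestors of a term are the
    nodes reachable from it.  ``broad_category`` optionally maps terms to a
    coarse category label used for partial-credit matching when neither term
    is an ancestor of the other.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    broad_category: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str]],
        broad_category: Optional[Mapping[str, str]] = None,
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        for term, name in terms.items():
            g.add_node(term, name=name)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in g:
                    raise OntologyError(f"edge ({child!r}, {parent!r}) references undeclared term {endpoint!r}")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        return cls(graph=g, broad_category=dict(broad_category or {}))

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def name_of(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def id_for_name(self, label: str) -> Optional[str]:
        wanted = normalize_label(label)
        hits = [t for t in self.graph.nodes if normalize_label(self.name_of(t)) == wanted]
        return min(hits) if hits else None

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors (transitive closure), excluding the term itself."""
        if term not in self.graph:
            return set()
        return set(nx.descendants(self.graph, term))

    def related_by_lineage(self, a: str, b: str) -> bool:
        """True when one term is an ancestor (any distance) of the other."""
        return a in self.ancestors(b) or b in self.ancestors(a)

    def same_broad_category(self, a: str, b: str) -> bool:
        cat_a = self.broad_category.get(a)
        return cat_a is not None and cat_a == self.broad_category.get(b)


def load_ontology(
    path: str | Path,
    format: Optional[str] = None,
    broad_category: Optional[Mapping[str, str]] = None,
) -> OntologyGraph:
    """Read an ontology from OBO (is_a edges) or a child/parent edge TSV."""
    path = Path(path)
    fmt = format or ("obo" if path.suffix == ".obo" else "edge_tsv")
    if fmt == "obo":
        import obonet

        multi = obonet.read_obo(str(path))
        terms = {t: data.get("name", t) for t, data in multi.nodes(data=True)}
        edges = [(u, v) for u, v, key in multi.edges(keys=True) if key == "is_a"]
        return OntologyGraph.from_edges(terms, edges, broad_category)
    if fmt == "edge_tsv":
        declared: dict[str, str] = {}
        raw_edges: list[tuple[str, str]] = []
        for raw in path.read_text().splitlines():
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in raw.split("\t")]
            child = cells[0]
            declared.setdefault(child, child)
            if len(cells) > 1 and cells[1]:
                raw_edges.append((child, cells[1]))
        return OntologyGraph.from_edges(declared, raw_edges, broad_category)
    raise ValueError(f"unknown ontology format: {fmt!r}")
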