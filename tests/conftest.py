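import numpy as np
import pytest

from cellscribe import (
    BiologicalContext,
    CountsWithClusters,
    GeneSetCollection,
    MarkerEntry,
    MarkerKnowledgeBase,
    OntologyGraph,
    demo_knowledge_base,
)


@pytest.fixture
def blood_kb() -> MarkerKnowledgeBase:
    """Five blood cell types with distinct markers and CL ids."""
    return demo_knowledge_base()


@pytest.fixture
def tiny_kb() -> MarkerKnowledgeBase:
    """Two-entry KB (one blood, one liver type) for plausibility tests."""
    return MarkerKnowledgeBase(
        [
            MarkerEntry(
                cell_type_name="B cell",
                cl_id="CL:0000236",
                broad_markers={"CD19", "MS4A1"},
                narrow_markers={"CD79B"},
                negative_markers={"ALB"},
                plausible_tissues={"blood"},
                plausible_states={"naive"},
                pathways_type={"B cell receptor signaling"},
                pathways_state={"antigen presentation"},
                synonyms={"B cells", "B-cell"},
            ),
            MarkerEntry(
                cell_type_name="hepatocyte",
                cl_id="CL:0000182",
                broad_markers={"ALB", "APOA1"},
                narrow_markers={"CYP3A4"},
                negative_markers={"CD19"},
                plausible_tissues={"liver"},
                plausible_states={"periportal@liver"},
                pathways_type={"bile acid metabolism"},
                pathways_state={"xenobiotic metabolism"},
                synonyms={"hepatocytes"},
            ),
        ]
    )


@pytest.fixture
def fixture_ontology() -> OntologyGraph:
    """Five-term CL-style DAG: cell → {lymphocyte → {T, B}, hepatocyte};
    CD8 T under T."""
    return OntologyGraph.from_edges(
        terms={
            "CL:0000000": "cell",
            "CL:0000542": "lymphocyte",
            "CL:0000084": "T cell",
            "CL:0000625": "CD8-positive T cell",
            "CL:0000236": "B cell",
            "CL:0000182": "hepatocyte",
        },
        edges=[
            ("CL:0000542", "CL:0000000"),
            ("CL:0000084", "CL:0000542"),
            ("CL:0000625", "CL:0000084"),
            ("CL:0000236", "CL:0000542"),
            ("CL:0000182", "CL:0000000"),
        ],
    )


@pytest.fixture
def blood_context() -> BiologicalContext:
    return BiologicalContext(tissue="blood", condition="healthy", species="human")


@pytest.fixture
def toy_counts() -> CountsWithClusters:
    """6 cells × 3 genes; G1 expressed only in cluster A (perfect separator)."""
    counts = np.array(
        [
            [9, 1, 5],
            [8, 2, 4],
            [7, 1, 6],
            [0, 2, 5],
            [0, 1, 4],
            [0, 3, 6],
        ]
    )
    return CountsWithClusters(
        counts=counts,
        gene_names=("G1", "G2", "G3"),
        cell_names=tuple(f"cell{i}" for i in range(6)),
        cluster_of=("A", "A", "A", "B", "B", "B"),
    )


@pytest.fixture
def small_gmt(tmp_path) -> GeneSetCollection:
    path = tmp_path / "sets.gmt"
    path.write_text(
        "bcr_signaling\tdesc\tCD19\tMS4A1\tCD79A\tCD79B\n"
        "bile_acid\tdesc\tALB\tAPOA1\tCYP3A4\n"
    )
    return GeneSetCollection.from_gmt(path)
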