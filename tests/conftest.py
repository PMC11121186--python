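"""Shared fixtures: tiny hand-built libraries and collections."""

from __future__ import annotations

import pytest

from dreamocracy.annotations import AnnotationLibrary, make_library
from dreamocracy.ingestion import DiseaseCollection, StudyDrugList


def build_collection(
    lists: dict[str, set[str]],
    disease: str = "ad",
    method: str = "CDRS",
) -> DiseaseCollection:
    """Collection from a {list_id: drug set} mapping (already canonical)."""
    return DiseaseCollection(
        disease=disease,
        method=method,
        lists=tuple(
            StudyDrugList(list_id=list_id, method=method, disease=disease, drugs=frozenset(drugs))
            for list_id, drugs in lists.items()
        ),
    )


@pytest.fixture
def micro_library() -> AnnotationLibrary:
    """Three drugs, two MoAs: the worked micro example."""
    return make_library(
        {
            "d1": {"moas": {"A"}},
            "d2": {"moas": {"A"}},
            "d3": {"moas": {"B"}},
        }
    )


@pytest.fixture
def micro_collection() -> DiseaseCollection:
    """Lists L1={d1,d2}, L2={d2,d3}, L3={d2}."""
    return build_collection({"L1": {"d1", "d2"}, "L2": {"d2", "d3"}, "L3": {"d2"}})


@pytest.fixture
def annotated_library() -> AnnotationLibrary:
    """Five drugs with all three modalities populated, for scoring tests."""
    return make_library(
        {
            "d1": {"moas": {"A"}, "indications": {"i1"}, "pathways": {"p1"}},
            "d2": {"moas": {"A", "B"}, "indications": {"i1", "i2"}, "pathways": {"p1", "p2"}},
            "d3": {"moas": {"B"}, "indications": {"i2"}, "pathways": {"p2"}},
            "d4": {"moas": {"C"}, "indications": {"i3"}, "pathways": {}},
            "d5": {"moas": {}, "indications": {}, "pathways": {}},
        }
    )
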