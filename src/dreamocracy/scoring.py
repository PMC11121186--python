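"""Scoring drugs against diseases from DC-matrices.

A drug's per-modality score is an aggregate (max by default) of the DC
scores of its *kept* features in the matrix; a drug with no kept features in
a modality scores 0 there, so the composite is defined for every library
drug.  The per-method Composite Score is a weighted sum

    Composite = W1 * ScoreOfPaths + W2 * ScoreOfMoAs + W3 * ScoreOfInds

with defaults 0.4/0.4/0.2 — pathways and mechanisms describe what the drug
does, the initial indication only what it was first used for.  The Total
Composite Score averages the Composite Scores over the collection methods
present (CDRS and CTS here, N adapts if one is missing).

The max aggregator is deliberate: it rewards one strong match and does not
dilute drugs with many annotations; the mean alternative is available via
``aggregator="mean"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import MODALITIES, AnnotationLibrary, DrugAnnotation, canonicalize_name
from .dcmatrix import DCMatrix
from .errors import DomainError

logger = logging.getLogger(__name__)

AGGREGATORS = ("max", "mean")


@dataclass(frozen=True)
class ModalityWeights:
    """Weights of the three per-modality scores in the Composite Score.

    Stored normalised to sum 1 (rescaled with a warning otherwise)."""

    w_paths: float = 0.4
    w_moas: float = 0.4
    w_inds: float = 0.2

    def __post_init__(self) -> None:
        if min(self.w_paths, self.w_moas, self.w_inds) < 0:
            raise DomainError("modality weights must be non-negative")
        total = self.w_paths + self.w_moas + self.w_inds
        if total <= 0:
            raise DomainError("modality weights must not all be zero")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(f"modality weights sum to {total:g}; rescaling to sum 1", stacklevel=2)
            object.__setattr__(self, "w_paths", self.w_paths / total)
            object.__setattr__(self, "w_moas", self.w_moas / total)
            object.__setattr__(self, "w_inds", self.w_inds / total)


@dataclass(frozen=True)
class DrugScore:
    """Per-drug, per-method score breakdown for one disease."""

    drug: str
    disease: str
    method: str
    score_paths: float
    score_moas: float
    score_inds: float
    composite: float


@dataclass(frozen=True)
class SuperReferenceTable:
    """Drugs x diseases table of per-method Composite Scores and Total
    Composite Scores.

    ``frame`` columns: drug, disease, one ``composite_<method>`` per method,
    ``total_composite``, ``n_methods``.
    """

    frame: pd.DataFrame
    methods: tuple[str, ...]
    weights: ModalityWeights
    aggregator: str
    provenance: Mapping[str, object] = field(default_factory=dict)

    def disease_ranking(self, disease: str, score: str = "total_composite") -> pd.DataFrame:
        """Rows of one disease sorted by a score column descending, ties by
        drug name ascending."""
        rows = self.frame[self.frame["disease"] == disease]
        return rows.sort_values([score, "drug"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def modality_score(
    drug: DrugAnnotation,
    matrix: DCMatrix,
    modality: str,
    aggregator: str = "max",
) -> float:
    """Aggregate the DC scores of a drug's kept features in one modality.

    Returns 0 if the drug has no kept features there (features filtered out
    by the enrichment test count as absent).
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")
    kept = matrix.kept_scores(modality)
    scores = [kept[f] for f in drug.features(modality) if f in kept]
    if not scores:
        return 0.0
    return max(scores) if aggregator == "max" else sum(scores) / len(scores)


def composite_score(
    score_paths: float,
    score_moas: float,
    score_inds: float,
    weights: ModalityWeights | None = None,
) -> float:
    """Weighted sum of the three per-modality scores (in [0, 1])."""
    weights = weights or ModalityWeights()
    for value in (score_paths, score_moas, score_inds):
        if not (0.0 <= value <= 1.0):
            raise DomainError(f"modality scores must be in [0,1]; got {value}")
    return weights.w_paths * score_paths + weights.w_moas * score_moas + weights.w_inds * score_inds


def total_composite_score(composites: Mapping[str, float]) -> float:
    """Arithmetic mean of the per-method Composite Scores present (N adapts
    to the methods available)."""
    if not composites:
        raise DomainError("total_composite_score requires at least one method")
    return sum(composites.values()) / len(composites)


def score_drug(
    drug: DrugAnnotation,
    matrix: DCMatrix,
    weights: ModalityWeights | None = None,
    aggregator: str = "max",
) -> DrugScore:
    """Full per-method score breakdown of one drug against one DC-matrix."""
    weights = weights or ModalityWeights()
    s_paths = modality_score(drug, matrix, "Path", aggregator)
    s_moas = modality_score(drug, matrix, "MoA", aggregator)
    s_inds = modality_score(drug, matrix, "Ind", aggregator)
    return DrugScore(
        drug=drug.name,
        disease=matrix.disease,
        method=matrix.method,
        score_paths=s_paths,
        score_moas=s_moas,
        score_inds=s_inds,
        composite=composite_score(s_paths, s_moas, s_inds, weights),
    )


def build_super_reference(
    library: AnnotationLibrary,
    matrices: Mapping[tuple[str, str], DCMatrix],
    weights: ModalityWeights | None = None,
    aggregator: str = "max",
) -> SuperReferenceTable:
    """Score every library drug against every disease with a matrix.

    Emits exactly one row per (drug, disease).  For diseases missing one
    collection method the total averages over the methods present and
    ``n_methods`` records how many contributed.
    """
    weights = weights or ModalityWeights()
    diseases = sorted({d for d, _ in matrices})
    methods = sorted({m for _, m in matrices})
    if not diseases:
        raise ValueError("no matrices supplied")
    rows = []
    for disease in diseases:
        present = {m: matrices[(disease, m)] for m in methods if (disease, m) in matrices}
        if not present:
            logger.warning("disease %s has no matrices; skipped", disease)
            continue
        # Pre-pull kept-score dicts once per matrix for speed.
        kept = {
            (method, modality): matrix.kept_scores(modality)
            for method, matrix in present.items()
            for modality in MODALITIES
        }
        for name in sorted(library.drugs):
            drug = library.drugs[name]
            composites: dict[str, float] = {}
            for method in present:
                per_modality = {}
                for modality in MODALITIES:
                    table = kept[(method, modality)]
                    scores = [table[f] for f in drug.features(modality) if f in table]
                    if not scores:
                        per_modality[modality] = 0.0
                    else:
                        per_modality[modality] = max(scores) if aggregator == "max" else sum(scores) / len(scores)
                composites[method] = composite_score(
                    per_modality["Path"], per_modality["MoA"], per_modality["Ind"], weights
                )
            row: dict[str, object] = {"drug": name, "disease": disease}
            for method in methods:
                row[f"composite_{method.lower()}"] = composites.get(method)
            row["total_composite"] = total_composite_score(composites)
            row["n_methods"] = len(composites)
            rows.append(row)
    frame = pd.DataFrame(rows)
    return SuperReferenceTable(
        frame=frame,
        methods=tuple(methods),
        weights=weights,
        aggregator=aggregator,
        provenance={"n_library_drugs": len(library), "diseases": diseases},
    )


def score_query(
    names: Sequence[str],
    table: SuperReferenceTable,
    disease: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Look up raw drug names in the super-reference table for one disease.

    Returns the matching rows (in input order, duplicates collapsed) and the
    list of names not found (canonicalised, input order preserved).
    """
    found_rows = []
    not_found: list[str] = []
    disease_frame = table.frame[table.frame["disease"] == disease].set_index("drug")
    seen: set[str] = set()
    for raw in names:
        name = canonicalize_name(raw)
        if name in seen:
            continue
        seen.add(name)
        if name in disease_frame.index:
            row = disease_frame.loc[name]
            found_rows.append({"drug": name, "disease": disease, **row.drop("disease").to_dict()})
        else:
            not_found.append(name)
    columns = ["drug", "disease"] + [c for c in table.frame.columns if c not in ("drug", "disease")]
    found = pd.DataFrame(found_rows, columns=columns)
    return found, not_found


def write_super_reference(table: SuperReferenceTable, path: str | Path) -> None:
    """Write the super-reference table as TSV plus a JSON sidecar."""
    import json

    path = Path(path)
    table.frame.to_csv(path, sep="\t", index=False)
    sidecar = {
        "methods": list(table.methods),
        "aggregator": table.aggregator,
        "weights": {
            "w_paths": table.weights.w_paths,
            "w_moas": table.weights.w_moas,
            "w_inds": table.weights.w_inds,
        },
        "provenance": dict(table.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_super_reference(path: str | Path) -> SuperReferenceTable:
    """Read back a super-reference table written by
    :func:`write_super_reference`."""
    import json

    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"drug": str, "disease": str})
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        return SuperReferenceTable(
            frame=frame,
            methods=tuple(sidecar["methods"]),
            weights=ModalityWeights(**sidecar["weights"]),
            aggregator=sidecar["aggregator"],
            provenance=sidecar.get("provenance", {}),
        )
    methods = tuple(
        c.removeprefix("composite_").upper() for c in frame.columns if c.startswith("composite_")
    )
    return SuperReferenceTable(frame=frame, methods=methods, weights=ModalityWeights(), aggregator="max")
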