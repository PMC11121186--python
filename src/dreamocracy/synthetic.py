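"""Synthetic benchmark generator with planted feature enrichment.

Generates an annotation library, gene sets and per-disease study-list
collections in exactly the formats the real readers consume, together with
the ground truth needed for recovery testing.  Planted features work through
drug sampling weights: drugs carrying a disease's planted features are
over-sampled into that disease's study lists by a factor ``enrichment``
(m = 1 means no signal), so a planted feature's drug frequency and list
count rise jointly — the same joint behaviour the DC score aggregates.

All randomness flows through one seeded :class:`numpy.random.Generator`
threaded explicitly through the operations; nothing touches global state,
and identical seeds give identical fixtures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotations import (
    AnnotationLibrary,
    DrugAnnotation,
    PathwayGeneSets,
    assign_pathways,
    write_annotation_table,
    write_gene_sets,
)
from .dcmatrix import DCMatrix
from .errors import ConfigError
from .ingestion import DiseaseCollection, StudyDrugList

logger = logging.getLogger(__name__)

#: Phases cycled over synthetic CTS lists.
_SYNTH_PHASES = ("phase 1", "phase 2", "phase 3", "phase 4")
_SYNTH_STATUSES = ("Completed", "Recruiting", "Active, not recruiting", "Not yet recruiting")

Count = "int | tuple[int, int]"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Per-drug sampling counts may be a fixed int or an inclusive (lo, hi)
    range.  ``planted`` pins planted feature labels per (disease, modality);
    if empty, ``n_planted`` MoA labels are drawn at random per disease.
    ``enrichment`` is the sampling-weight multiplier m >= 1 for drugs
    carrying a planted feature of the disease being sampled.
    """

    n_drugs: int = 300
    n_moas: int = 30
    n_inds: int = 25
    n_pathways: int = 20
    n_genes: int = 200
    genes_per_pathway: int = 15
    moas_per_drug: object = 2
    inds_per_drug: object = 2
    targets_per_drug: object = 3
    n_lists: int = 6
    list_size: int = 40
    diseases: tuple[str, ...] = ("disease-a",)
    methods: tuple[str, ...] = ("CDRS",)
    planted: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    n_planted: int = 5
    enrichment: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_moas", "n_inds", "n_pathways", "n_genes", "genes_per_pathway", "n_lists", "list_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.enrichment < 1:
            raise ConfigError(f"enrichment must be >= 1 (m={self.enrichment})")
        if self.list_size > self.n_drugs:
            raise ConfigError(f"list_size={self.list_size} exceeds n_drugs={self.n_drugs}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulation: planted feature labels per
    (disease, method, modality) and carrier drugs per disease."""

    planted: Mapping[tuple[str, str, str], frozenset[str]]
    carriers: Mapping[str, frozenset[str]]


def _draw_count(spec: object, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec  # type: ignore[misc]
    return int(rng.integers(lo, hi + 1))


def generate_library(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AnnotationLibrary, PathwayGeneSets]:
    """Generate the annotation universe: drugs with uniformly sampled MoAs,
    indications and targets, plus gene sets; pathways are derived through
    the same target-membership rule the real pipeline uses."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _check_universe(config)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    moa_labels = [f"moa-{i:03d}" for i in range(config.n_moas)]
    ind_labels = [f"ind-{i:03d}" for i in range(config.n_inds)]
    path_labels = [f"path-{i:03d}" for i in range(config.n_pathways)]

    sets = {
        label: frozenset(genes[j] for j in rng.choice(config.n_genes, size=config.genes_per_pathway, replace=False))
        for label in path_labels
    }
    gene_sets = PathwayGeneSets(sets=sets)

    drugs: dict[str, DrugAnnotation] = {}
    for i in range(config.n_drugs):
        name = f"drug-{i:04d}"
        k_moa = _draw_count(config.moas_per_drug, rng)
        k_ind = _draw_count(config.inds_per_drug, rng)
        k_tgt = _draw_count(config.targets_per_drug, rng)
        drugs[name] = DrugAnnotation(
            name=name,
            moas=frozenset(moa_labels[j] for j in rng.choice(config.n_moas, size=k_moa, replace=False)),
            indications=frozenset(ind_labels[j] for j in rng.choice(config.n_inds, size=k_ind, replace=False)),
            targets=frozenset(genes[j] for j in rng.choice(config.n_genes, size=k_tgt, replace=False)),
        )
    library = AnnotationLibrary(drugs=drugs)
    return assign_pathways(library, gene_sets), gene_sets


def _check_universe(config: SimulationConfig) -> None:
    def upper(spec: object) -> int:
        return spec if isinstance(spec, int) else spec[1]  # type: ignore[index]

    if upper(config.moas_per_drug) > config.n_moas:
        raise ConfigError("moas_per_drug exceeds n_moas")
    if upper(config.inds_per_drug) > config.n_inds:
        raise ConfigError("inds_per_drug exceeds n_inds")
    if upper(config.targets_per_drug) > config.n_genes:
        raise ConfigError("targets_per_drug exceeds n_genes")
    if config.genes_per_pathway > config.n_genes:
        raise ConfigError("genes_per_pathway exceeds n_genes")


def _choose_planted(
    config: SimulationConfig,
    library: AnnotationLibrary,
    rng: np.random.Generator,
) -> dict[tuple[str, str], frozenset[str]]:
    """Planted labels per (disease, modality): explicit config wins, else
    ``n_planted`` random MoA labels per disease."""
    if config.planted:
        out = {}
        for (disease, modality), labels in config.planted.items():
            universe = library.universe(modality)
            missing = set(labels) - universe
            if missing:
                raise ConfigError(f"planted features {sorted(missing)} absent from {modality} universe")
            out[(disease, modality)] = frozenset(labels)
        return out
    moa_universe = sorted(library.universe("MoA"))
    if config.n_planted > len(moa_universe):
        raise ConfigError("n_planted exceeds the MoA universe")
    return {
        (disease, "MoA"): frozenset(
            moa_universe[j] for j in rng.choice(len(moa_universe), size=config.n_planted, replace=False)
        )
        for disease in config.diseases
    }


def generate_collections(
    library: AnnotationLibrary,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], DiseaseCollection], PlantedTruth]:
    """Sample study lists with planted enrichment.

    Each list draws ``list_size`` drugs without replacement with weight 1
    for non-carriers and ``enrichment`` for carriers of the disease's
    planted features.  CTS lists additionally carry per-drug phases.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = sorted(library.drugs)
    planted = _choose_planted(config, library, rng)

    carriers: dict[str, frozenset[str]] = {}
    for disease in config.diseases:
        hit: set[str] = set()
        for (d, modality), labels in planted.items():
            if d != disease:
                continue
            for name in names:
                if library.drugs[name].features(modality) & labels:
                    hit.add(name)
        carriers[disease] = frozenset(hit)

    collections: dict[tuple[str, str], DiseaseCollection] = {}
    for disease in config.diseases:
        weights = np.array([config.enrichment if n in carriers[disease] else 1.0 for n in names])
        probabilities = weights / weights.sum()
        for method in config.methods:
            lists = []
            for j in range(config.n_lists):
                idx = rng.choice(len(names), size=config.list_size, replace=False, p=probabilities)
                drugs = frozenset(names[i] for i in idx)
                phases: dict[str, str] = {}
                if method == "CTS":
                    phase = _SYNTH_PHASES[j % len(_SYNTH_PHASES)]
                    phases = {d: phase for d in sorted(drugs)}
                lists.append(
                    StudyDrugList(
                        list_id=f"{disease}-{method.lower()}-{j + 1:02d}",
                        method=method,
                        disease=disease,
                        drugs=drugs,
                        per_drug_phase=phases,
                    )
                )
            collections[(disease, method)] = DiseaseCollection(disease=disease, method=method, lists=tuple(lists))

    truth = PlantedTruth(
        planted={
            (disease, method, modality): labels
            for (disease, modality), labels in planted.items()
            for method in config.methods
        },
        carriers=carriers,
    )
    return collections, truth


def simulate(
    config: SimulationConfig,
) -> tuple[AnnotationLibrary, PathwayGeneSets, dict[tuple[str, str], DiseaseCollection], PlantedTruth]:
    """One-call simulation: library + gene sets + collections + truth, all
    driven by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    library, gene_sets = generate_library(config, rng)
    collections, truth = generate_collections(library, config, rng)
    return library, gene_sets, collections, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall of planted features among the top-ranked kept
    features of one modality."""

    modality: str
    precision: float
    recall: float
    top_j: int
    degenerate: bool = False


def recovery_metrics(
    matrix: DCMatrix,
    truth: PlantedTruth,
    top_j: int,
) -> dict[str, RecoveryMetrics]:
    """Planted-feature recovery in a DC-matrix.

    For each modality with planted features, takes the ``top_j`` kept
    features ranked by DC score (the matrix order) and reports precision and
    recall of the planted set.  An empty kept table yields (0, 0) with the
    ``degenerate`` flag set; ``top_j`` larger than the kept table is clamped
    with a warning.
    """
    out: dict[str, RecoveryMetrics] = {}
    for (disease, method, modality), labels in truth.planted.items():
        if disease != matrix.disease or method != matrix.method:
            continue
        kept = list(matrix.modality_entries(modality, kept_only=True)["feature"])
        if not kept:
            out[modality] = RecoveryMetrics(modality=modality, precision=0.0, recall=0.0, top_j=0, degenerate=True)
            continue
        j = top_j
        if j > len(kept):
            logger.warning("top_j=%d exceeds %d kept %s features; clamped", top_j, len(kept), modality)
            j = len(kept)
        top = set(kept[:j])
        hits = len(top & labels)
        out[modality] = RecoveryMetrics(
            modality=modality,
            precision=hits / j,
            recall=hits / len(labels),
            top_j=j,
        )
    return out


def write_fixture_files(
    library: AnnotationLibrary,
    gene_sets: PathwayGeneSets,
    collections: Mapping[tuple[str, str], DiseaseCollection],
    truth: PlantedTruth,
    out_dir: str | Path,
) -> dict[str, object]:
    """Write fixtures in the formats the real readers consume.

    Emits a hub-dialect library TSV, a GMT file, one text file per CDRS
    list, one registry-style trials CSV per disease holding the CTS lists
    (with deliberately discardable ``Terminated`` decoy trials and a
    lower-phase duplicate trial to exercise the ingestion rules), and a
    truth JSON.  Returns a manifest of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {}

    library_path = out_dir / "library.tsv"
    write_annotation_table(library, library_path)
    manifest["library"] = str(library_path)

    gmt_path = out_dir / "gene_sets.gmt"
    write_gene_sets(gene_sets, gmt_path)
    manifest["gene_sets"] = str(gmt_path)

    cdrs_paths: dict[str, list[str]] = {}
    cts_paths: dict[str, str] = {}
    for (disease, method), collection in sorted(collections.items()):
        if method == "CDRS":
            for lst in collection.lists:
                path = out_dir / f"{lst.list_id}.txt"
                path.write_text("\n".join(sorted(lst.drugs)) + "\n")
                cdrs_paths.setdefault(disease, []).append(str(path))
        elif method == "CTS":
            path = out_dir / f"{disease}-trials.csv"
            _write_trials_csv(collection, path)
            cts_paths[disease] = str(path)
    manifest["cdrs_lists"] = cdrs_paths
    manifest["cts_trials"] = cts_paths

    truth_path = out_dir / "truth.json"
    truth_payload = {
        "planted": {
            "|".join(key): sorted(labels) for key, labels in sorted(truth.planted.items())
        },
        "carriers": {disease: sorted(drugs) for disease, drugs in sorted(truth.carriers.items())},
    }
    truth_path.write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    manifest["truth"] = str(truth_path)
    return manifest


def _write_trials_csv(collection: DiseaseCollection, path: Path) -> None:
    import csv

    rows = []
    counter = 1
    for j, lst in enumerate(collection.lists):
        interventions = "|".join(f"Drug: {d}" for d in sorted(lst.drugs))
        phase = next(iter(lst.per_drug_phase.values()), "phase 2") if lst.per_drug_phase else "phase 2"
        rows.append(
            {
                "NCT Number": f"NCT{counter:08d}",
                "Status": _SYNTH_STATUSES[j % len(_SYNTH_STATUSES)],
                "Phases": phase,
                "Interventions": interventions,
            }
        )
        counter += 1
    # Decoy trials: discarded status, and a duplicate drug at a lower phase.
    some_drug = sorted(collection.lists[0].drugs)[0]
    rows.append(
        {
            "NCT Number": f"NCT{counter:08d}",
            "Status": "Terminated",
            "Phases": "phase 3",
            "Interventions": f"Drug: {some_drug}|Device: stimulator",
        }
    )
    counter += 1
    rows.append(
        {
            "NCT Number": f"NCT{counter:08d}",
            "Status": "Completed",
            "Phases": "early phase 1",
            "Interventions": f"Drug: {some_drug}|Behavioral: exercise",
        }
    )
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=["NCT Number", "Status", "Phases", "Interventions"])
        writer.writeheader()
        writer.writerows(rows)
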