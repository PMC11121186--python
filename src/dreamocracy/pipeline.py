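"""Configuration-driven orchestration: ingest -> DC-matrices -> super
reference -> comparisons, with a provenance manifest.

The run configuration is a JSON (or YAML) document naming the input files,
the equation weights, the significance threshold and the aggregator.  All
outputs are deterministic given identical inputs and configuration; the
manifest records SHA-256 digests of every input so any change is
detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from . import __version__
from .annotations import assign_pathways, load_annotation_table, load_gene_sets, load_synonyms
from .comparison import (
    disease_commonality_network,
    network_edge_list,
    overlap_report,
    top_k_common_drugs,
    top_k_report,
)
from .dcmatrix import DEFAULT_ALPHA, FeatureWeights, build_dc_matrix, write_dc_matrix
from .errors import ConfigError
from .ingestion import (
    build_cts_lists,
    load_trials_csv,
    parse_drug_list,
    resolve_collection,
    write_collection,
    write_unmatched_report,
)
from .scoring import ModalityWeights, build_super_reference, write_super_reference

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "library",
    "gene_sets",
    "synonyms",
    "diseases",
    "methods",
    "cdrs_lists",
    "cts_trials",
    "w_freq",
    "w_listcount",
    "w_paths",
    "w_moas",
    "w_inds",
    "alpha",
    "aggregator",
    "top_k",
    "seed",
    "out_dir",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    library: str
    gene_sets: str
    out_dir: str
    diseases: list[str]
    methods: list[str] = field(default_factory=lambda: ["CDRS", "CTS"])
    cdrs_lists: Mapping[str, list[str]] = field(default_factory=dict)
    cts_trials: Mapping[str, str] = field(default_factory=dict)
    synonyms: str | None = None
    w_freq: float = 0.4
    w_listcount: float = 0.6
    w_paths: float = 0.4
    w_moas: float = 0.4
    w_inds: float = 0.2
    alpha: float = DEFAULT_ALPHA
    aggregator: str = "max"
    top_k: int = 100
    seed: int = 0


def load_config(path: str | Path) -> dict:
    """Parse a JSON or YAML configuration file into a raw dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return raw


def validate_config(raw: Mapping[str, object]) -> tuple[RunConfig, list[str]]:
    """Validate a raw config dict: fill defaults, rescale non-normalised
    weights (warning), reject unknown keys and negative weights."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("library", "gene_sets", "out_dir", "diseases"):
        if key not in raw:
            raise ConfigError(f"config is missing required key {key!r}")
    config = RunConfig(**{k: v for k, v in raw.items()})  # type: ignore[arg-type]
    notes: list[str] = []
    for name in ("w_freq", "w_listcount", "w_paths", "w_moas", "w_inds", "alpha"):
        if getattr(config, name) < 0:
            raise ConfigError(f"{name} must be non-negative")
    pair = config.w_freq + config.w_listcount
    if pair <= 0:
        raise ConfigError("w_freq and w_listcount must not both be zero")
    if abs(pair - 1.0) > 1e-9:
        notes.append(f"feature weights rescaled from ({config.w_freq:g}, {config.w_listcount:g}) to sum 1")
        config.w_freq, config.w_listcount = config.w_freq / pair, config.w_listcount / pair
    triple = config.w_paths + config.w_moas + config.w_inds
    if triple <= 0:
        raise ConfigError("modality weights must not all be zero")
    if abs(triple - 1.0) > 1e-9:
        notes.append("modality weights rescaled to sum 1")
        config.w_paths /= triple
        config.w_moas /= triple
        config.w_inds /= triple
    if config.aggregator not in ("max", "mean"):
        raise ConfigError(f"unknown aggregator {config.aggregator!r}")
    for note in notes:
        logger.warning(note)
    return config, notes


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest.

    Outputs are written under ``config.out_dir``; any stage failure raises
    :class:`StageError` after renaming that stage's partial outputs with a
    ``.partial`` suffix.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "inputs": {}, "outputs": [], "timings": {}, "versions": {}}
    import pandas, numpy, scipy  # noqa: PLC0415

    manifest["versions"] = {
        "dreamocracy": __version__,
        "pandas": pandas.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    stage_files: list[Path] = []

    def record_output(path: Path) -> Path:
        stage_files.append(path)
        manifest["outputs"].append(str(path))
        return path

    def run_stage(name: str, fn):
        nonlocal stage_files
        stage_files = []
        start = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # tag and keep partial outputs visible
            for path in stage_files:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise StageError(name, exc) from exc
        manifest["timings"][name] = round(time.perf_counter() - start, 6)
        return result

    # --- load ---------------------------------------------------------
    def stage_load():
        for key in ("library", "gene_sets", "synonyms"):
            value = getattr(config, key)
            if value is None:
                continue
            path = Path(value)
            if not path.exists():
                raise FileNotFoundError(f"{key} file not found: {path}")
            manifest["inputs"][str(path)] = _sha256(path)
        synonyms = load_synonyms(config.synonyms) if config.synonyms else None
        library = load_annotation_table(config.library, dialect="hub", synonyms=synonyms)
        gene_sets = load_gene_sets(config.gene_sets)
        return assign_pathways(library, gene_sets)

    library = run_stage("load", stage_load)

    # --- ingest -------------------------------------------------------
    def stage_ingest():
        collections = {}
        for disease in config.diseases:
            if "CDRS" in config.methods and disease in config.cdrs_lists:
                lists = []
                for list_path in config.cdrs_lists[disease]:
                    path = Path(list_path)
                    if not path.exists():
                        raise FileNotFoundError(f"CDRS list not found: {path}")
                    manifest["inputs"][str(path)] = _sha256(path)
                    lists.append(parse_drug_list(path, disease=disease))
                collections[(disease, "CDRS")] = resolve_collection(lists, library)
            if "CTS" in config.methods and disease in config.cts_trials:
                path = Path(config.cts_trials[disease])
                if not path.exists():
                    raise FileNotFoundError(f"CTS trials file not found: {path}")
                manifest["inputs"][str(path)] = _sha256(path)
                records = load_trials_csv(path)
                lists = build_cts_lists(records, disease=disease)
                collections[(disease, "CTS")] = resolve_collection(lists, library)
        if not collections:
            raise ConfigError("no collections could be built from the config")
        for (disease, method), collection in sorted(collections.items()):
            write_collection(collection, record_output(out_dir / f"collection_{disease}_{method}.tsv"))
            if collection.unmatched:
                write_unmatched_report(collection, record_output(out_dir / f"unmatched_{disease}_{method}.tsv"))
        return collections

    collections = run_stage("ingest", stage_ingest)

    # --- matrices -----------------------------------------------------
    def stage_matrices():
        weights = FeatureWeights(config.w_freq, config.w_listcount)
        matrices = {}
        for key, collection in sorted(collections.items()):
            matrix = build_dc_matrix(collection, library, weights=weights, alpha=config.alpha)
            matrices[key] = matrix
            path = record_output(out_dir / f"dcmatrix_{key[0]}_{key[1]}.tsv")
            write_dc_matrix(matrix, path)
            record_output(path.with_suffix(path.suffix + ".json"))
        return matrices

    matrices = run_stage("matrices", stage_matrices)

    # --- super-reference ---------------------------------------------
    def stage_super():
        weights = ModalityWeights(config.w_paths, config.w_moas, config.w_inds)
        table = build_super_reference(library, matrices, weights=weights, aggregator=config.aggregator)
        path = record_output(out_dir / "super_reference.tsv")
        write_super_reference(table, path)
        record_output(path.with_suffix(path.suffix + ".json"))
        return table

    table = run_stage("super_reference", stage_super)

    # --- comparisons --------------------------------------------------
    def stage_compare():
        backgrounds = {m: len(library.universe(m)) for m in ("MoA", "Ind", "Path")}
        methods_present = sorted({m for _, m in matrices})
        if len(methods_present) == 2:
            report = overlap_report(matrices, backgrounds, *methods_present)
            if not report.empty:
                report.to_csv(record_output(out_dir / "overlap_report.tsv"), sep="\t", index=False)
        for method in methods_present:
            diseases = {d for d, m in matrices if m == method}
            if len(diseases) >= 2:
                edges = disease_commonality_network(matrices, method)
                network_edge_list(edges).to_csv(
                    record_output(out_dir / f"network_{method}.tsv"), sep="\t", index=False
                )
        if table.frame["disease"].nunique() >= 2:
            common = top_k_common_drugs(table, "total", k=config.top_k)
            top_k_report(common).to_csv(record_output(out_dir / "topk_total.tsv"), sep="\t", index=False)

    run_stage("compare", stage_compare)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
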