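"""Drug annotation universe: loading, canonicalisation, pathway mapping.

The annotation library (modelled on the Drug Repurposing Hub export format)
is the background population for every frequency and enrichment computation
downstream.  Each drug record carries its mechanisms of action (MoAs), the
initial indications (Inds) it was developed for, its protein targets, and the
targeted pathways (Paths) derived from target membership in gene sets.

Drug names are matched deterministically after canonicalisation (lowercase,
trimmed, unicode dashes folded to ASCII); an optional alias table supplements
this.  There is deliberately no fuzzy matching — silent membership changes
would be worse than an unmatched report.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyLibraryError, GMTParseError, InvalidNameError, SchemaError

logger = logging.getLogger(__name__)

#: Annotation modalities scored by the method.
MODALITIES = ("MoA", "Ind", "Path")

#: Modality label -> DrugAnnotation attribute holding the feature set.
MODALITY_ATTR = {"MoA": "moas", "Ind": "indications", "Path": "pathways"}

# Unicode hyphen/dash variants folded to the ASCII hyphen-minus.
_DASH_TRANSLATION = str.maketrans({c: "-" for c in "‐‑‒–—―−"})
_WHITESPACE_RUN = re.compile(r"\s+")

#: Multi-value cell separator in hub-style tables.
MULTIVALUE_SEP = "|"


def canonicalize_name(raw: str) -> str:
    """Return the canonical form of a drug name.

    Lowercases, trims, collapses internal whitespace runs to a single space
    and maps unicode en/em dashes to the ASCII hyphen, so that e.g.
    ``"pipotiazine–palmitate"`` (en dash) and ``"Pipotiazine-Palmitate"``
    resolve to the same key.

    Raises
    ------
    InvalidNameError
        If the name is empty after trimming.
    """
    if raw is None:
        raise InvalidNameError("drug name is None")
    name = raw.translate(_DASH_TRANSLATION)
    name = _WHITESPACE_RUN.sub(" ", name).strip().lower()
    if not name:
        raise InvalidNameError(f"drug name empty after trimming: {raw!r}")
    return name


@dataclass(frozen=True)
class DrugAnnotation:
    """One canonical drug record.

    ``pathways`` is always derived: exactly the gene-set labels whose members
    intersect ``targets`` (see :func:`assign_pathways`).
    """

    name: str
    moas: frozenset[str] = frozenset()
    targets: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    smiles: str | None = None
    clinical_phase: str | None = None

    def features(self, modality: str) -> frozenset[str]:
        """Feature set of this drug for a modality (``MoA``/``Ind``/``Path``)."""
        try:
            return getattr(self, MODALITY_ATTR[modality])
        except KeyError:
            raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}") from None


@dataclass(frozen=True)
class PathwayGeneSets:
    """Pathway label -> set of (uppercase) gene symbols."""

    sets: Mapping[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class AnnotationLibrary:
    """The full drug annotation universe.

    ``drugs`` maps canonical name -> record; ``synonyms`` maps alias
    (canonical form) -> canonical drug name.
    """

    drugs: Mapping[str, DrugAnnotation]
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {c for c in self.synonyms.values() if c not in self.drugs}
        if missing:
            raise ValueError(f"synonyms point at unknown drugs: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.drugs)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.drugs

    def resolve(self, raw: str) -> str | None:
        """Canonical drug key for a raw name, via canonicalisation then
        synonyms; ``None`` if unknown."""
        name = canonicalize_name(raw)
        if name in self.drugs:
            return name
        return self.synonyms.get(name)

    def universe(self, modality: str) -> frozenset[str]:
        """All feature labels of a modality observed across the library."""
        out: set[str] = set()
        for drug in self.drugs.values():
            out |= drug.features(modality)
        return frozenset(out)

    def feature_carrier_counts(self, modality: str) -> dict[str, int]:
        """Feature label -> number of library drugs annotated with it."""
        counts: dict[str, int] = {}
        for drug in self.drugs.values():
            for feat in drug.features(modality):
                counts[feat] = counts.get(feat, 0) + 1
        return counts


def _split_multivalue(cell: str) -> frozenset[str]:
    if not cell or not cell.strip():
        return frozenset()
    return frozenset(p.strip() for p in cell.split(MULTIVALUE_SEP) if p.strip())


_HUB_COLUMNS = {"name": "name", "moa": "moa", "target": "target", "indication": "indication"}
_HUB_OPTIONAL = {"smiles": "smiles", "clinical_phase": "clinical_phase", "pathway": "pathway"}


def load_annotation_table(
    path: str | Path,
    dialect: str = "hub",
    column_map: Mapping[str, str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> AnnotationLibrary:
    """Load a drug annotation table.

    Parameters
    ----------
    path
        TSV (``hub`` dialect: tab-separated, ``!`` comment lines, ``|`` as
        multi-value separator) or CSV/TSV (``generic`` dialect).
    dialect
        ``"hub"`` or ``"generic"``.  The generic dialect requires
        ``column_map`` mapping the logical fields ``name``/``moa``/``target``/
        ``indication`` (optionally ``smiles``/``clinical_phase``) to column
        names of the file.
    synonyms
        Optional alias -> canonical-name map attached to the library.

    Rows sharing a canonical name are merged by set union (hub-style exports
    repeat drugs); the merge count is logged.
    """
    path = Path(path)
    if dialect == "hub":
        colmap = dict(_HUB_COLUMNS)
        optional = dict(_HUB_OPTIONAL)
        frame = pd.read_csv(path, sep="\t", comment="!", dtype=str, keep_default_na=False)
        if "name" not in frame.columns and "pert_iname" in frame.columns:
            colmap["name"] = "pert_iname"
    elif dialect == "generic":
        if column_map is None:
            raise SchemaError("generic dialect requires a column_map")
        colmap = {k: v for k, v in column_map.items() if k in _HUB_COLUMNS}
        optional = {k: v for k, v in column_map.items() if k in _HUB_OPTIONAL}
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'hub' or 'generic'")

    for logical, column in colmap.items():
        if column not in frame.columns:
            raise SchemaError(f"annotation table {path} is missing required column {column!r} ({logical})")
    optional = {k: v for k, v in optional.items() if v in frame.columns}

    drugs: dict[str, DrugAnnotation] = {}
    merged = 0
    for _, row in frame.iterrows():
        raw_name = row[colmap["name"]]
        if not str(raw_name).strip():
            continue
        name = canonicalize_name(str(raw_name))
        record = DrugAnnotation(
            name=name,
            moas=_split_multivalue(row[colmap["moa"]]),
            targets=frozenset(t.upper() for t in _split_multivalue(row[colmap["target"]])),
            indications=_split_multivalue(row[colmap["indication"]]),
            pathways=_split_multivalue(row[optional["pathway"]]) if "pathway" in optional else frozenset(),
            smiles=(row[optional["smiles"]].strip() or None) if "smiles" in optional else None,
            clinical_phase=(row[optional["clinical_phase"]].strip() or None)
            if "clinical_phase" in optional
            else None,
        )
        if name in drugs:
            prev = drugs[name]
            record = DrugAnnotation(
                name=name,
                moas=prev.moas | record.moas,
                targets=prev.targets | record.targets,
                indications=prev.indications | record.indications,
                pathways=prev.pathways | record.pathways,
                smiles=prev.smiles or record.smiles,
                clinical_phase=prev.clinical_phase or record.clinical_phase,
            )
            merged += 1
        drugs[name] = record

    if not drugs:
        raise EmptyLibraryError(f"annotation table {path} yielded zero parseable drug rows")
    logger.info("loaded %d rows -> %d drugs (%d merged) from %s", len(frame), len(drugs), merged, path)
    return AnnotationLibrary(drugs=drugs, synonyms=dict(synonyms or {}))


def write_annotation_table(library: AnnotationLibrary, path: str | Path) -> None:
    """Write a normalized hub-dialect TSV (one row per drug, pipe-joined
    sets, sorted for byte-stable provenance output)."""
    path = Path(path)
    columns = ["name", "clinical_phase", "moa", "target", "indication", "smiles", "pathway"]
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for name in sorted(library.drugs):
            drug = library.drugs[name]
            writer.writerow(
                [
                    name,
                    drug.clinical_phase or "",
                    MULTIVALUE_SEP.join(sorted(drug.moas)),
                    MULTIVALUE_SEP.join(sorted(drug.targets)),
                    MULTIVALUE_SEP.join(sorted(drug.indications)),
                    drug.smiles or "",
                    MULTIVALUE_SEP.join(sorted(drug.pathways)),
                ]
            )


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Load a two-column (alias, canonical) CSV into a canonicalised map."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise SchemaError(f"synonym file {path} needs two columns (alias, canonical)")
    alias_col, canon_col = frame.columns[:2]
    return {
        canonicalize_name(a): canonicalize_name(c)
        for a, c in zip(frame[alias_col], frame[canon_col])
        if str(a).strip() and str(c).strip()
    }


def load_gene_sets(path: str | Path) -> PathwayGeneSets:
    """Parse a GMT gene-set file.

    Each line is ``label<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    labels are merged by union (logged); gene symbols are uppercased.

    Raises
    ------
    GMTParseError
        On any line with fewer than three fields, naming the line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GMTParseError(f"{path}:{lineno}: GMT line has {len(parts)} fields, expected >= 3")
            label, _description, *gene_cells = parts
            genes = {g.strip().upper() for g in gene_cells if g.strip()}
            if not genes:
                raise GMTParseError(f"{path}:{lineno}: gene set {label!r} has no genes")
            if label in sets:
                logger.info("GMT %s:%d: duplicate label %r merged by union", path, lineno, label)
                sets[label] |= genes
            else:
                sets[label] = genes
    return PathwayGeneSets(sets={k: frozenset(v) for k, v in sets.items()})


def write_gene_sets(gene_sets: PathwayGeneSets, path: str | Path) -> None:
    """Write gene sets back out as GMT (sorted, for stable fixtures)."""
    with open(path, "w", newline="") as handle:
        for label in sorted(gene_sets.sets):
            handle.write("\t".join([label, "na", *sorted(gene_sets.sets[label])]) + "\n")


def assign_pathways(library: AnnotationLibrary, gene_sets: PathwayGeneSets) -> AnnotationLibrary:
    """Derive each drug's targeted pathways from its targets.

    A drug is a member of pathway P exactly when at least one of its targets
    is in P's gene set (plain membership union, no enrichment gating).
    Drugs without targets get an empty pathway set; their count is logged.
    """
    if not gene_sets.sets:
        raise ValueError("gene_sets is empty")
    gene_index: dict[str, set[str]] = {}
    for label, genes in gene_sets.sets.items():
        for gene in genes:
            gene_index.setdefault(gene, set()).add(label)

    drugs: dict[str, DrugAnnotation] = {}
    targetless = 0
    for name, drug in library.drugs.items():
        if not drug.targets:
            targetless += 1
            pathways: frozenset[str] = frozenset()
        else:
            hit: set[str] = set()
            for gene in drug.targets:
                hit |= gene_index.get(gene, set())
            pathways = frozenset(hit)
        drugs[name] = replace(drug, pathways=pathways)
    if targetless:
        logger.info("assign_pathways: %d/%d drugs have no targets (empty pathway sets)", targetless, len(drugs))
    return AnnotationLibrary(drugs=drugs, synonyms=dict(library.synonyms))


def make_library(
    records: Iterable[DrugAnnotation] | Mapping[str, Mapping[str, Iterable[str]]],
    synonyms: Mapping[str, str] | None = None,
) -> AnnotationLibrary:
    """Build a library programmatically.

    Accepts either an iterable of :class:`DrugAnnotation` or a mapping
    ``name -> {"moas": [...], "targets": [...], "indications": [...]}``
    (convenient in tests and fixtures).
    """
    drugs: dict[str, DrugAnnotation] = {}
    if isinstance(records, Mapping):
        for raw_name, spec in records.items():
            name = canonicalize_name(raw_name)
            drugs[name] = DrugAnnotation(
                name=name,
                moas=frozenset(spec.get("moas", ())),
                targets=frozenset(t.upper() for t in spec.get("targets", ())),
                indications=frozenset(spec.get("indications", ())),
                pathways=frozenset(spec.get("pathways", ())),
                smiles=spec.get("smiles"),
                clinical_phase=spec.get("clinical_phase"),
            )
    else:
        for record in records:
            drugs[record.name] = record
    return AnnotationLibrary(drugs=drugs, synonyms=dict(synonyms or {}))
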