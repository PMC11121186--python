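"""Study drug-list ingestion.

Two collection methods feed the scoring pipeline:

* **CDRS** — computational drug repurposing studies: one file per published
  study, either plain text (one drug per line) or CSV with a drug-name
  column.  The file stem is the study/list identity.
* **CTS** — clinical trial studies: a registry CSV export (status, phases,
  interventions).  Trials with status Suspended/Withdrawn/Terminated are
  discarded, only ``Drug:`` interventions are kept, and each drug is kept
  once at its highest trial phase.  The retained trial is the study unit.

Lists are then resolved against the annotation library: drugs the library
does not know are removed and reported, never silently kept, because every
downstream score needs annotations.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import AnnotationLibrary, canonicalize_name
from .errors import EmptyListError, SchemaError, UnusableCollectionError

logger = logging.getLogger(__name__)

#: Registry phase labels in ascending order; "na"/unknown rank lowest.
PHASE_ORDER = (
    "na",
    "early phase 1",
    "phase 1",
    "phase 1/phase 2",
    "phase 2",
    "phase 2/phase 3",
    "phase 3",
    "phase 4",
)

_KEPT_STATUSES = {
    "completed",
    "actively recruiting",
    "recruiting",
    "not yet recruiting",
    "active not recruiting",
}

#: Fewer lists than this triggers a reliability warning (not an error).
MIN_RECOMMENDED_LISTS = 3


def _normalize_status(status: str) -> str:
    return " ".join(str(status).replace(",", " ").split()).lower()


def normalize_phase(phase: str | None) -> str:
    """Map a raw phase cell to a label of :data:`PHASE_ORDER` ("na" for
    blank/not-applicable)."""
    if phase is None:
        return "na"
    text = " ".join(str(phase).split()).lower()
    if text in {"", "na", "n/a", "not applicable", "nan"}:
        return "na"
    # registry exports sometimes separate combined phases with '|'
    text = text.replace("|", "/").replace(" / ", "/")
    return text


def phase_rank(phase: str | None) -> int:
    """Ordinal rank of a phase label; unknown labels rank lowest (warned)."""
    label = normalize_phase(phase)
    try:
        return PHASE_ORDER.index(label)
    except ValueError:
        logger.warning("unknown phase label %r treated as lowest rank", phase)
        return 0


@dataclass(frozen=True)
class TrialRecord:
    """One registry trial row (already column-mapped)."""

    trial_id: str
    status: str
    phase: str
    interventions: str


@dataclass(frozen=True)
class StudyDrugList:
    """One study's drug list (a CDRS file or one retained trial)."""

    list_id: str
    method: str  # "CDRS" | "CTS"
    disease: str
    drugs: frozenset[str]
    per_drug_phase: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DiseaseCollection:
    """A disease's study lists for one collection method, resolved against
    an annotation library; ``unmatched`` maps raw name -> list ids."""

    disease: str
    method: str
    lists: tuple[StudyDrugList, ...]
    unmatched: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def drug_union(self) -> frozenset[str]:
        out: set[str] = set()
        for lst in self.lists:
            out |= lst.drugs
        return frozenset(out)


def parse_drug_list(
    path: str | Path,
    disease: str,
    list_id: str | None = None,
    method: str = "CDRS",
    drug_column: str | None = None,
) -> StudyDrugList:
    """Parse one study drug-list file (plain text or CSV).

    Plain text: one drug per line, blank lines skipped.  CSV: the drug
    column is ``drug_column`` if given, else the first of
    ``drug``/``drug_name``/``name`` present.

    Raises
    ------
    EmptyListError
        If zero drugs remain after parsing.
    """
    path = Path(path)
    list_id = list_id or path.stem
    names: list[str] = []
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        column = drug_column
        if column is None:
            for candidate in ("drug", "drug_name", "name"):
                if candidate in frame.columns:
                    column = candidate
                    break
        if column is None or column not in frame.columns:
            raise SchemaError(f"drug list {path} has no recognisable drug-name column")
        names = [v for v in frame[column] if str(v).strip()]
    else:
        with open(path) as handle:
            names = [line.strip() for line in handle if line.strip()]
    drugs = frozenset(canonicalize_name(n) for n in names)
    if not drugs:
        raise EmptyListError(f"drug list {path} contains no drugs")
    return StudyDrugList(list_id=list_id, method=method, disease=disease, drugs=drugs)


_TRIAL_COLUMN_CANDIDATES = {
    "trial_id": ("NCT Number", "nct_number", "trial_id"),
    "status": ("Status", "Study Status", "status"),
    "phase": ("Phases", "Phase", "phase"),
    "interventions": ("Interventions", "interventions"),
}


def load_trials_csv(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[TrialRecord]:
    """Read a ClinicalTrials.gov-style CSV export into trial records.

    ``column_map`` may pin logical fields (``trial_id``/``status``/``phase``/
    ``interventions``) to column names; otherwise the registry's historical
    spellings are tried.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    resolved: dict[str, str] = {}
    for logical, candidates in _TRIAL_COLUMN_CANDIDATES.items():
        if column_map and logical in column_map:
            column = column_map[logical]
            if column not in frame.columns:
                raise SchemaError(f"trials file {path} is missing mapped column {column!r} ({logical})")
        else:
            column = next((c for c in candidates if c in frame.columns), None)
            if column is None:
                raise SchemaError(f"trials file {path} is missing a column for {logical!r} (tried {candidates})")
        resolved[logical] = column
    records = []
    for _, row in frame.iterrows():
        trial_id = str(row[resolved["trial_id"]]).strip()
        if not trial_id:
            continue
        records.append(
            TrialRecord(
                trial_id=trial_id,
                status=str(row[resolved["status"]]),
                phase=str(row[resolved["phase"]]),
                interventions=str(row[resolved["interventions"]]),
            )
        )
    return records


def filter_trials(records: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Keep trials whose status is Completed / (Actively) Recruiting /
    Not yet recruiting / Active not recruiting; drop all others
    (Suspended, Withdrawn, Terminated, ...).  Case- and comma-insensitive."""
    kept = [r for r in records if _normalize_status(r.status) in _KEPT_STATUSES]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("filter_trials: dropped %d/%d trials by status", dropped, len(records))
    return kept


def extract_drug_interventions(record: TrialRecord) -> frozenset[str]:
    """Names of ``Drug:`` items in a trial's pipe-separated interventions
    cell; other intervention types (Behavioral, Device, Biological, ...) are
    ignored, unparseable items skipped with a warning."""
    names: set[str] = set()
    for item in str(record.interventions).split("|"):
        item = item.strip()
        if not item:
            continue
        kind, sep, name = item.partition(":")
        if not sep or not name.strip():
            logger.warning("trial %s: unparseable intervention item %r skipped", record.trial_id, item)
            continue
        if kind.strip().lower() == "drug":
            names.add(name.strip())
    return frozenset(names)


def dedupe_highest_phase(
    records: Sequence[tuple[str, str, str]],
) -> dict[str, tuple[str, str]]:
    """Collapse (drug, phase, trial_id) tuples to one entry per drug at its
    highest phase; ties keep the first occurrence in input order."""
    best: dict[str, tuple[str, str]] = {}
    for drug, phase, trial_id in records:
        if drug not in best or phase_rank(phase) > phase_rank(best[drug][0]):
            best[drug] = (phase, trial_id)
    return best


def build_cts_lists(
    records: Sequence[TrialRecord],
    disease: str,
) -> list[StudyDrugList]:
    """Turn registry trial records into CTS study lists.

    Applies the status filter, extracts drug interventions, keeps each drug
    once at its highest phase, then groups the retained drugs by the trial
    that carried them (one study list per retained trial, ordered by first
    appearance in the export).
    """
    kept = filter_trials(records)
    flat: list[tuple[str, str, str]] = []
    for record in kept:
        for raw in sorted(extract_drug_interventions(record)):
            flat.append((canonicalize_name(raw), normalize_phase(record.phase), record.trial_id))
    best = dedupe_highest_phase(flat)
    by_trial: dict[str, dict[str, str]] = {}
    for drug, (phase, trial_id) in best.items():
        by_trial.setdefault(trial_id, {})[drug] = phase
    order = {r.trial_id: i for i, r in enumerate(kept)}
    lists = [
        StudyDrugList(
            list_id=trial_id,
            method="CTS",
            disease=disease,
            drugs=frozenset(drugs),
            per_drug_phase=dict(sorted(drugs.items())),
        )
        for trial_id, drugs in sorted(by_trial.items(), key=lambda kv: order.get(kv[0], len(order)))
    ]
    return lists


def resolve_collection(
    lists: Sequence[StudyDrugList],
    library: AnnotationLibrary,
) -> DiseaseCollection:
    """Resolve study lists against the annotation library.

    Drugs unknown to the library (after canonicalisation and synonyms) are
    removed and recorded in ``unmatched``; lists emptied by resolution are
    dropped with a warning.  Fewer than :data:`MIN_RECOMMENDED_LISTS`
    surviving lists triggers a reliability warning, not an error.

    Raises
    ------
    UnusableCollectionError
        If every list is empty after resolution.
    """
    if not lists:
        raise UnusableCollectionError("no study lists supplied")
    disease = lists[0].disease
    method = lists[0].method
    unmatched: dict[str, list[str]] = {}
    resolved: list[StudyDrugList] = []
    for lst in lists:
        if lst.disease != disease or lst.method != method:
            raise ValueError("all lists of a collection must share disease and method")
        kept: set[str] = set()
        phases: dict[str, str] = {}
        for drug in sorted(lst.drugs):
            canonical = library.resolve(drug)
            if canonical is None:
                unmatched.setdefault(drug, []).append(lst.list_id)
            else:
                kept.add(canonical)
                if drug in lst.per_drug_phase:
                    phases[canonical] = lst.per_drug_phase[drug]
        if kept:
            resolved.append(
                StudyDrugList(
                    list_id=lst.list_id,
                    method=method,
                    disease=disease,
                    drugs=frozenset(kept),
                    per_drug_phase=phases,
                )
            )
        else:
            logger.warning("list %s empty after library resolution; dropped", lst.list_id)
    if not resolved:
        raise UnusableCollectionError(f"collection {disease}/{method}: all lists empty after resolution")
    if len(resolved) < MIN_RECOMMENDED_LISTS:
        logger.warning(
            "collection %s/%s has %d lists (< %d recommended); scores may be unreliable",
            disease,
            method,
            len(resolved),
            MIN_RECOMMENDED_LISTS,
        )
    return DiseaseCollection(
        disease=disease,
        method=method,
        lists=tuple(resolved),
        unmatched={k: tuple(v) for k, v in unmatched.items()},
    )


def write_collection(collection: DiseaseCollection, path: str | Path) -> None:
    """Write a resolved collection as TSV (disease, method, list_id, drug,
    phase)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease", "method", "list_id", "drug", "phase"])
        for lst in collection.lists:
            for drug in sorted(lst.drugs):
                writer.writerow(
                    [collection.disease, collection.method, lst.list_id, drug, lst.per_drug_phase.get(drug, "")]
                )


def write_unmatched_report(collection: DiseaseCollection, path: str | Path) -> None:
    """Write the unmatched raw names with the lists they occurred in."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease", "method", "raw_name", "list_ids"])
        for raw in sorted(collection.unmatched):
            writer.writerow([collection.disease, collection.method, raw, ";".join(collection.unmatched[raw])])


def read_collection(path: str | Path) -> DiseaseCollection:
    """Read back a collection TSV written by :func:`write_collection`.

    The file is trusted to be already resolved (drug names canonical)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in ("disease", "method", "list_id", "drug"):
        if column not in frame.columns:
            raise SchemaError(f"collection file {path} is missing column {column!r}")
    if frame.empty:
        raise UnusableCollectionError(f"collection file {path} is empty")
    disease = frame["disease"].iloc[0]
    method = frame["method"].iloc[0]
    lists = []
    for list_id, group in frame.groupby("list_id", sort=False):
        phases = {}
        if "phase" in group.columns:
            phases = {d: p for d, p in zip(group["drug"], group["phase"]) if p}
        lists.append(
            StudyDrugList(
                list_id=str(list_id),
                method=method,
                disease=disease,
                drugs=frozenset(group["drug"]),
                per_drug_phase=phases,
            )
        )
    return DiseaseCollection(disease=disease, method=method, lists=tuple(lists))
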