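"""Disease/collection reference score matrices (DC-matrices).

For one disease and one collection method, every annotation feature (MoA,
initial indication, targeted pathway) observed across the study lists is
scored by weight-modulated majority voting:

    DC = W_F * NormFreq + W_LC * NormListCount

where ``Freq`` counts the distinct collection drugs carrying the feature,
``ListCount`` counts the study lists containing at least one such drug, and
both are normalised by their per-modality maximum over the unfiltered table
(so the feature maximal in both metrics scores exactly 1).  The default
weights put more mass on ListCount (0.6 vs 0.4): seeing a signature in many
independent studies counts for more than its within-study frequency.

Features are then pruned by an exact hypergeometric enrichment test against
the annotation library background (strictly p < alpha, default 0.05), which
removes features that could plausibly appear by random draws of collection
drugs from the library.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotations import MODALITIES, AnnotationLibrary
from .errors import DomainError
from .ingestion import DiseaseCollection

logger = logging.getLogger(__name__)

#: Columns of the per-feature entry table, in output order.
ENTRY_COLUMNS = (
    "modality",
    "feature",
    "freq",
    "list_count",
    "norm_freq",
    "norm_listcount",
    "dc_score",
    "p_value",
    "kept",
)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class FeatureWeights:
    """Weights of normalised frequency vs normalised list count.

    Stored normalised to sum 1; non-normalised input is rescaled with a
    warning, negative weights are rejected.
    """

    w_freq: float = 0.4
    w_listcount: float = 0.6

    def __post_init__(self) -> None:
        if self.w_freq < 0 or self.w_listcount < 0:
            raise DomainError("feature weights must be non-negative")
        total = self.w_freq + self.w_listcount
        if total <= 0:
            raise DomainError("feature weights must not both be zero")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(f"feature weights sum to {total:g}; rescaling to sum 1", stacklevel=2)
            object.__setattr__(self, "w_freq", self.w_freq / total)
            object.__setattr__(self, "w_listcount", self.w_listcount / total)


@dataclass(frozen=True)
class DCMatrix:
    """Per-disease, per-method feature score table.

    ``entries`` holds one row per (modality, feature) with counts, normalised
    values, DC score, enrichment p-value and the kept flag (dropped features
    stay in the table with ``kept=False`` for audit).
    """

    disease: str
    method: str
    weights: FeatureWeights
    alpha: float
    entries: pd.DataFrame
    provenance: Mapping[str, object] = field(default_factory=dict)

    def modality_entries(self, modality: str, kept_only: bool = False) -> pd.DataFrame:
        frame = self.entries[self.entries["modality"] == modality]
        if kept_only:
            frame = frame[frame["kept"]]
        return frame

    def kept_scores(self, modality: str) -> dict[str, float]:
        """Feature -> DC score for the kept features of a modality."""
        frame = self.modality_entries(modality, kept_only=True)
        return dict(zip(frame["feature"], frame["dc_score"]))

    def kept_features(self, modality: str) -> frozenset[str]:
        return frozenset(self.modality_entries(modality, kept_only=True)["feature"])


def count_features(
    collection: DiseaseCollection,
    library: AnnotationLibrary,
    modality: str,
) -> list[tuple[str, int, int]]:
    """Count per-feature ``freq`` and ``list_count`` over a collection.

    ``freq`` is the number of distinct drugs in the union of lists that are
    annotated with the feature (a drug counts once however many lists repeat
    it); ``list_count`` is the number of lists containing at least one such
    drug.  Features with zero frequency are absent.  Returned sorted by
    feature label for determinism.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    feature_drugs: dict[str, set[str]] = {}
    feature_lists: dict[str, set[str]] = {}
    for lst in collection.lists:
        for drug in lst.drugs:
            record = library.drugs.get(drug)
            if record is None:
                raise KeyError(f"collection drug {drug!r} missing from library; resolve the collection first")
            for feat in record.features(modality):
                feature_drugs.setdefault(feat, set()).add(drug)
                feature_lists.setdefault(feat, set()).add(lst.list_id)
    return [(feat, len(feature_drugs[feat]), len(feature_lists[feat])) for feat in sorted(feature_drugs)]


def normalize_unit_interval(
    counts: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int, int, float, float]]:
    """Divide each metric by its maximum over the (unfiltered) table, so all
    normalised values lie in (0, 1] and at least one feature attains 1."""
    if not counts:
        return []
    max_freq = max(c[1] for c in counts)
    max_lc = max(c[2] for c in counts)
    return [(feat, freq, lc, freq / max_freq, lc / max_lc) for feat, freq, lc in counts]


def dc_score(norm_freq: float, norm_listcount: float, weights: FeatureWeights | None = None) -> float:
    """Weight-modulated majority-voting score of one feature:
    ``w_freq * norm_freq + w_listcount * norm_listcount`` (in [0, 1])."""
    weights = weights or FeatureWeights()
    if not (0.0 <= norm_freq <= 1.0 and 0.0 <= norm_listcount <= 1.0):
        raise DomainError(f"normalised inputs must be in [0,1]; got ({norm_freq}, {norm_listcount})")
    return weights.w_freq * norm_freq + weights.w_listcount * norm_listcount


def hypergeom_pvalue(k: int, K: int, n: int, M: int) -> float:
    """Exact upper-tail enrichment probability P(X >= k) for X ~
    Hypergeometric(M, K, n).

    ``M`` is the library size, ``K`` the library drugs carrying the feature,
    ``n`` the distinct collection drugs, ``k`` the collection drugs carrying
    the feature.  Computed with exact integer arithmetic (tail sum of
    binomial-coefficient products), so the only error is one float rounding.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("M", M)):
        if int(value) != value or value < 0:
            raise DomainError(f"{name} must be a non-negative integer, got {value!r}")
    k, K, n, M = int(k), int(K), int(n), int(M)
    if K > M or n > M:
        raise DomainError(f"K={K} and n={n} must not exceed M={M}")
    if k > min(K, n):
        raise DomainError(f"k={k} exceeds min(K={K}, n={n})")
    if k < max(0, n - (M - K)):
        # lower support bound: every draw beyond the non-carriers is a carrier
        return 1.0
    numerator = sum(comb(K, i) * comb(M - K, n - i) for i in range(k, min(K, n) + 1))
    return numerator / comb(M, n)


def filter_matrix(entries: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Set the ``kept`` flag: strictly ``p_value < alpha`` (a p-value equal
    to alpha is excluded).  Scores are never altered; dropped rows remain in
    the table for audit."""
    out = entries.copy()
    out["kept"] = out["p_value"] < alpha
    return out


def build_dc_matrix(
    collection: DiseaseCollection,
    library: AnnotationLibrary,
    weights: FeatureWeights | None = None,
    alpha: float = DEFAULT_ALPHA,
    modalities: Sequence[str] = MODALITIES,
) -> DCMatrix:
    """Build the DC-matrix for a resolved collection.

    Per modality: count -> normalise -> DC score -> exact hypergeometric
    p-value against the library background -> strict filter.  Entries are
    sorted by DC score descending, ties by feature label ascending.
    """
    weights = weights or FeatureWeights()
    if not collection.lists:
        raise ValueError("collection has no lists")
    n_collection = len(collection.drug_union())
    m_library = len(library)
    rows: list[dict[str, object]] = []
    for modality in modalities:
        counts = count_features(collection, library, modality)
        if not counts:
            logger.warning("collection %s/%s: no %s features observed", collection.disease, collection.method, modality)
            continue
        carrier_counts = library.feature_carrier_counts(modality)
        for feat, freq, lc, nf, nlc in normalize_unit_interval(counts):
            rows.append(
                {
                    "modality": modality,
                    "feature": feat,
                    "freq": freq,
                    "list_count": lc,
                    "norm_freq": nf,
                    "norm_listcount": nlc,
                    "dc_score": dc_score(nf, nlc, weights),
                    "p_value": hypergeom_pvalue(freq, carrier_counts[feat], n_collection, m_library),
                }
            )
    entries = pd.DataFrame(rows, columns=[c for c in ENTRY_COLUMNS if c != "kept"])
    entries["kept"] = False
    if not entries.empty:
        entries = filter_matrix(entries, alpha)
        entries = entries.sort_values(
            ["modality", "dc_score", "feature"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
    return DCMatrix(
        disease=collection.disease,
        method=collection.method,
        weights=weights,
        alpha=alpha,
        entries=entries,
        provenance={
            "n_collection_drugs": n_collection,
            "n_library_drugs": m_library,
            "list_ids": [lst.list_id for lst in collection.lists],
        },
    )


def write_dc_matrix(matrix: DCMatrix, path: str | Path) -> None:
    """Write the DC-matrix as TSV plus a JSON sidecar (weights, alpha,
    provenance) next to it."""
    import json

    path = Path(path)
    out = matrix.entries.copy()
    out.insert(0, "disease", matrix.disease)
    out.insert(1, "method", matrix.method)
    out.to_csv(path, sep="\t", index=False)
    sidecar = {
        "disease": matrix.disease,
        "method": matrix.method,
        "weights": {"w_freq": matrix.weights.w_freq, "w_listcount": matrix.weights.w_listcount},
        "alpha": matrix.alpha,
        "provenance": dict(matrix.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_dc_matrix(path: str | Path) -> DCMatrix:
    """Read back a DC-matrix written by :func:`write_dc_matrix`."""
    import json

    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"feature": str, "modality": str})
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        weights = FeatureWeights(**sidecar["weights"])
        alpha = sidecar["alpha"]
        disease = sidecar["disease"]
        method = sidecar["method"]
        provenance = sidecar.get("provenance", {})
    else:
        weights = FeatureWeights()
        alpha = DEFAULT_ALPHA
        disease = str(frame["disease"].iloc[0])
        method = str(frame["method"].iloc[0])
        provenance = {}
    entries = frame.drop(columns=[c for c in ("disease", "method") if c in frame.columns])
    return DCMatrix(disease=disease, method=method, weights=weights, alpha=alpha, entries=entries, provenance=provenance)
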