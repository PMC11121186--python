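"""Comparative analyses over DC-matrices and super-reference tables.

Covers the cross-method and cross-disease questions the scoring pipeline
raises: do the computational-study (CDRS) and clinical-trial (CTS) signatures
of a disease overlap more than chance (exact hypergeometric test against the
library's modality universe)?  Which features do disease pairs share
(disease-disease commonality network)?  How much do top-k drug rankings
overlap?  Do the normalised frequencies of the two collection methods agree
(ordinary least squares)?  And do score distributions of drug groups differ
(Wilcoxon signed-rank for paired groups, rank-sum for independent ones)?
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dcmatrix import DCMatrix, hypergeom_pvalue
from .errors import DegenerateTestError, DomainError, UndefinedResultError
from .scoring import SuperReferenceTable

logger = logging.getLogger(__name__)

#: Sample-size bounds for the exact branches of the Wilcoxon tests.
SIGNED_RANK_EXACT_MAX_N = 25
RANK_SUM_EXACT_MAX_MIN_N = 10


@dataclass(frozen=True)
class SignatureOverlap:
    """Overlap of two feature signatures with its enrichment p-value."""

    modality: str
    features_a: frozenset[str]
    features_b: frozenset[str]
    common: frozenset[str]
    background_size: int
    p_value: float


@dataclass(frozen=True)
class DiseaseEdge:
    """Unordered disease pair with per-modality shared kept-feature counts."""

    disease_a: str
    disease_b: str
    shared: Mapping[str, int]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group score comparison."""

    label_a: str
    label_b: str
    statistic: float
    p_value: float
    paired: bool
    n_a: int
    n_b: int
    test: str
    method: str  # "exact" | "approx"


def signature_overlap(
    sig_a: Sequence[str] | frozenset[str],
    sig_b: Sequence[str] | frozenset[str],
    background_size: int,
    modality: str = "",
) -> SignatureOverlap:
    """Exact hypergeometric test of the overlap of two signatures.

    The background is the annotation library's modality universe; drawing
    ``|sig_b|`` features at random from it, the p-value is the probability
    of hitting at least ``|sig_a ∩ sig_b|`` members of ``sig_a``.  Symmetric
    in the two signatures.
    """
    set_a, set_b = frozenset(sig_a), frozenset(sig_b)
    if max(len(set_a), len(set_b)) > background_size:
        raise DomainError(
            f"signature sizes ({len(set_a)}, {len(set_b)}) exceed background {background_size}"
        )
    common = set_a & set_b
    p = hypergeom_pvalue(len(common), len(set_a), len(set_b), background_size)
    return SignatureOverlap(
        modality=modality,
        features_a=set_a,
        features_b=set_b,
        common=frozenset(common),
        background_size=background_size,
        p_value=p,
    )


def disease_commonality_network(
    matrices: Mapping[tuple[str, str], DCMatrix],
    method: str,
) -> list[DiseaseEdge]:
    """Per-modality shared kept-feature counts for every unordered disease
    pair under one collection method (all-zero edges included)."""
    diseases = sorted({d for (d, m) in matrices if m == method})
    if len(diseases) < 2:
        raise ValueError(f"need >= 2 diseases with {method} matrices, have {len(diseases)}")
    modalities = ("MoA", "Ind", "Path")
    kept = {d: {mod: matrices[(d, method)].kept_features(mod) for mod in modalities} for d in diseases}
    edges = []
    for a, b in itertools.combinations(diseases, 2):
        shared = {mod: len(kept[a][mod] & kept[b][mod]) for mod in modalities}
        edges.append(DiseaseEdge(disease_a=a, disease_b=b, shared=shared))
    return edges


def top_k_common_drugs(
    table: SuperReferenceTable,
    method_scope: str = "total",
    k: int = 100,
) -> dict[tuple[str, ...], frozenset[str]]:
    """Common drugs among every disease subset's top-k ranking.

    ``method_scope`` selects the ranking score: ``"total"`` for the Total
    Composite Score or a method name (e.g. ``"CDRS"``) for that method's
    Composite Score.  Ties at the k-th score are broken by drug name
    ascending so exactly k rows are taken; diseases with fewer than k rows
    use all of them (warned).  Intersections are reported for every disease
    subset of size >= 2.
    """
    score_col = "total_composite" if method_scope == "total" else f"composite_{method_scope.lower()}"
    if score_col not in table.frame.columns:
        raise ValueError(f"score column {score_col!r} not in super-reference table")
    diseases = sorted(table.frame["disease"].unique())
    top: dict[str, frozenset[str]] = {}
    for disease in diseases:
        ranking = table.disease_ranking(disease, score=score_col)
        if len(ranking) < k:
            logger.warning("disease %s has %d rows (< k=%d); using all", disease, len(ranking), k)
        top[disease] = frozenset(ranking["drug"].head(k))
    out: dict[tuple[str, ...], frozenset[str]] = {}
    for size in range(2, len(diseases) + 1):
        for subset in itertools.combinations(diseases, size):
            common = frozenset.intersection(*(top[d] for d in subset))
            out[subset] = common
    return out


def frequency_concordance(
    freqs_a: Mapping[str, float],
    freqs_b: Mapping[str, float],
) -> tuple[float, float, float, int]:
    """Ordinary least squares of b's normalised frequencies on a's over
    their common features: returns (slope, intercept, r_squared, n_common).

    Raises
    ------
    UndefinedResultError
        With fewer than 3 common features or a constant predictor.
    """
    common = sorted(set(freqs_a) & set(freqs_b))
    if len(common) < 3:
        raise UndefinedResultError(f"only {len(common)} common features; need >= 3 for a regression")
    x = np.array([freqs_a[f] for f in common], dtype=float)
    y = np.array([freqs_b[f] for f in common], dtype=float)
    if np.ptp(x) == 0:
        raise UndefinedResultError("predictor frequencies are constant; slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2, len(common)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def _exact_signed_rank_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Midranks handle tied magnitudes, so this is the permutation distribution
    conditional on the observed magnitudes; p = min(1, 2 * min tail).
    Returns (statistic min(W+, W-), p).  Feasible well past n = 25 because
    the distribution is built by dynamic programming, not enumeration.
    """
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    total = float(ranks.sum())
    # doubling midranks makes every rank an exact integer
    doubled = np.rint(2 * ranks).astype(int)
    counts = np.zeros(doubled.sum() + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    n_assignments = 2.0 ** len(diffs)
    w2 = int(round(2 * w_plus))
    p_low = counts[: w2 + 1].sum() / n_assignments
    p_high = counts[w2:].sum() / n_assignments
    return min(w_plus, total - w_plus), min(1.0, 2 * min(p_low, p_high))


def compare_score_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    paired: bool,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided Wilcoxon comparison of two score groups.

    Paired groups (e.g. the same drugs under CDRS vs CTS reference tables)
    use the signed-rank test: zero differences are dropped, the exact null
    distribution is used for n <= 25 without tied absolute differences, and
    the normal approximation with continuity correction otherwise.
    Independent groups use the rank-sum (Mann-Whitney) test, exact for
    min(n) <= 10 without ties.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise DomainError(f"paired comparison needs equal lengths, got {len(a)} vs {len(b)}")
        d = b - a
        d = d[d != 0]
        if len(d) == 0:
            raise DegenerateTestError("all paired differences are zero; signed-rank test undefined")
        if len(d) < 2:
            raise DegenerateTestError(f"only {len(d)} nonzero paired differences; need >= 2")
        exact = len(d) <= SIGNED_RANK_EXACT_MAX_N
        if exact:
            statistic, p_value = _exact_signed_rank_p(d)
        else:
            result = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
            statistic, p_value = float(result.statistic), float(result.pvalue)
        return GroupComparison(
            label_a=label_a,
            label_b=label_b,
            statistic=float(statistic),
            p_value=float(p_value),
            paired=True,
            n_a=len(a),
            n_b=len(b),
            test="wilcoxon-signed-rank",
            method="exact" if exact else "approx",
        )
    if len(a) == 0 or len(b) == 0:
        raise DomainError("unpaired comparison needs two nonempty groups")
    pooled = np.concatenate([a, b])
    exact = min(len(a), len(b)) <= RANK_SUM_EXACT_MAX_MIN_N and not _has_ties(pooled)
    result = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        paired=False,
        n_a=len(a),
        n_b=len(b),
        test="wilcoxon-rank-sum",
        method="exact" if exact else "approx",
    )


# ---------------------------------------------------------------------------
# Plot-ready exports


def overlap_report(
    matrices: Mapping[tuple[str, str], DCMatrix],
    background_sizes: Mapping[str, int],
    method_a: str = "CDRS",
    method_b: str = "CTS",
) -> pd.DataFrame:
    """Signature-overlap table (disease, modality, sizes, p) between two
    collection methods, for every disease holding both matrices.

    ``background_sizes`` maps modality -> library universe size.
    """
    rows = []
    diseases = sorted({d for (d, m) in matrices})
    for disease in diseases:
        if (disease, method_a) not in matrices or (disease, method_b) not in matrices:
            continue
        for modality in ("MoA", "Ind", "Path"):
            sig_a = matrices[(disease, method_a)].kept_features(modality)
            sig_b = matrices[(disease, method_b)].kept_features(modality)
            overlap = signature_overlap(sig_a, sig_b, background_sizes[modality], modality=modality)
            rows.append(
                {
                    "disease": disease,
                    "modality": modality,
                    "n_a": len(sig_a),
                    "n_b": len(sig_b),
                    "n_common": len(overlap.common),
                    "background": overlap.background_size,
                    "p_value": overlap.p_value,
                }
            )
    return pd.DataFrame(rows, columns=["disease", "modality", "n_a", "n_b", "n_common", "background", "p_value"])


def network_edge_list(edges: Sequence[DiseaseEdge]) -> pd.DataFrame:
    """Flatten disease edges to a (source, target, modality, count) table."""
    rows = [
        {"source": e.disease_a, "target": e.disease_b, "modality": mod, "count": count}
        for e in edges
        for mod, count in sorted(e.shared.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "modality", "count"])


def top_k_report(common: Mapping[tuple[str, ...], frozenset[str]]) -> pd.DataFrame:
    """Flatten top-k intersections to a (diseases, n_common, drugs) table."""
    rows = [
        {"diseases": ";".join(subset), "n_common": len(drugs), "drugs": ";".join(sorted(drugs))}
        for subset, drugs in sorted(common.items())
    ]
    return pd.DataFrame(rows, columns=["diseases", "n_common", "drugs"])
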