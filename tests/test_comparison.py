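"""Comparative analyses: signature overlap, disease networks, top-k drug
overlap, frequency regression, group score tests."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from dreamocracy.comparison import (
    compare_score_groups,
    disease_commonality_network,
    frequency_concordance,
    signature_overlap,
    top_k_common_drugs,
)
from dreamocracy.dcmatrix import build_dc_matrix
from dreamocracy.errors import DegenerateTestError, DomainError, UndefinedResultError
from dreamocracy.scoring import ModalityWeights, SuperReferenceTable
from tests.conftest import build_collection


class TestSignatureOverlap:
    def test_worked_tail_sum(self) -> None:
        # |A|=5, |B|=4, overlap 3, background 20:
        # p = [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4) = 155/4845
        sig_a = {f"a{i}" for i in range(2)} | {"c1", "c2", "c3"}
        sig_b = {"b1"} | {"c1", "c2", "c3"}
        out = signature_overlap(sig_a, sig_b, 20)
        assert len(out.common) == 3
        assert out.p_value == pytest.approx(155 / 4845, abs=1e-12)

    def test_disjoint_sets_p_one(self) -> None:
        assert signature_overlap({"a"}, {"b"}, 20).p_value == 1.0

    def test_identical_sets_single_term(self) -> None:
        sig = {f"f{i}" for i in range(5)}
        assert signature_overlap(sig, sig, 20).p_value == pytest.approx(1 / comb(20, 5), abs=1e-12)

    def test_symmetry(self) -> None:
        sig_a = {"x", "y", "z", "w"}
        sig_b = {"x", "y", "q"}
        assert signature_overlap(sig_a, sig_b, 30).p_value == pytest.approx(
            signature_overlap(sig_b, sig_a, 30).p_value, rel=1e-12
        )

    def test_p_decreases_as_overlap_grows(self) -> None:
        background = 25
        previous = 1.1
        for overlap in range(0, 5):
            sig_a = {f"c{i}" for i in range(overlap)} | {f"a{i}" for i in range(4 - overlap)}
            sig_b = {f"c{i}" for i in range(overlap)} | {f"b{i}" for i in range(5 - overlap)}
            p = signature_overlap(sig_a, sig_b, background).p_value
            assert p <= previous + 1e-12
            previous = p

    def test_oversized_signature_rejected(self) -> None:
        with pytest.raises(DomainError):
            signature_overlap({f"f{i}" for i in range(30)}, {"a"}, 20)


class TestDiseaseNetwork:
    def matrices(self, annotated_library):
        specs = {
            "ad": {"L1": {"d1", "d2"}, "L2": {"d2"}},
            "pd": {"L1": {"d2", "d3"}, "L2": {"d3"}},
            "hd": {"L1": {"d4"}, "L2": {"d4"}},
        }
        return {
            (disease, "CDRS"): build_dc_matrix(
                build_collection(lists, disease=disease), annotated_library, alpha=1.01
            )
            for disease, lists in specs.items()
        }

    def test_counts_match_brute_force(self, annotated_library) -> None:
        matrices = self.matrices(annotated_library)
        edges = {(e.disease_a, e.disease_b): e.shared for e in disease_commonality_network(matrices, "CDRS")}
        assert len(edges) == 3  # C(3,2) pairs
        for (a, b), shared in edges.items():
            for modality in ("MoA", "Ind", "Path"):
                expected = len(
                    matrices[(a, "CDRS")].kept_features(modality) & matrices[(b, "CDRS")].kept_features(modality)
                )
                assert shared[modality] == expected

    def test_shared_and_zero_edges(self, annotated_library) -> None:
        matrices = self.matrices(annotated_library)
        edges = {(e.disease_a, e.disease_b): e.shared for e in disease_commonality_network(matrices, "CDRS")}
        # ad and pd share d2/d3's annotations; hd (only d4) shares nothing
        assert edges[("ad", "pd")]["MoA"] >= 1
        assert edges[("ad", "hd")] == {"MoA": 0, "Ind": 0, "Path": 0}

    def test_single_disease_rejected(self, annotated_library) -> None:
        matrices = {k: v for k, v in self.matrices(annotated_library).items() if k[0] == "ad"}
        with pytest.raises(ValueError):
            disease_commonality_network(matrices, "CDRS")


def make_table(scores: dict[str, dict[str, float]]) -> SuperReferenceTable:
    rows = [
        {"drug": drug, "disease": disease, "composite_cdrs": s, "composite_cts": s,
         "total_composite": s, "n_methods": 2}
        for disease, per_drug in scores.items()
        for drug, s in per_drug.items()
    ]
    return SuperReferenceTable(
        frame=pd.DataFrame(rows), methods=("CDRS", "CTS"), weights=ModalityWeights(), aggregator="max"
    )


class TestTopKCommonDrugs:
    def test_identical_rankings_full_overlap(self) -> None:
        scores = {f"drug{i:02d}": (20 - i) / 20 for i in range(15)}
        table = make_table({"ad": scores, "pd": dict(scores)})
        common = top_k_common_drugs(table, "total", k=10)
        assert len(common[("ad", "pd")]) == 10

    def test_constructed_overlap_of_three(self) -> None:
        ad = {f"shared{i}": 0.9 - i * 0.01 for i in range(3)}
        ad.update({f"ad{i}": 0.8 - i * 0.01 for i in range(7)})
        ad.update({f"low{i}": 0.1 for i in range(5)})
        pd_scores = {f"shared{i}": 0.9 - i * 0.01 for i in range(3)}
        pd_scores.update({f"pd{i}": 0.8 - i * 0.01 for i in range(7)})
        pd_scores.update({f"low{i}": 0.05 for i in range(5)})
        table = make_table({"ad": ad, "pd": pd_scores})
        common = top_k_common_drugs(table, "total", k=10)
        assert common[("ad", "pd")] == {"shared0", "shared1", "shared2"}

    def test_k_larger_than_table_clamps_with_warning(self, caplog) -> None:
        table = make_table({"ad": {"a": 0.5}, "pd": {"a": 0.4}})
        with caplog.at_level("WARNING"):
            common = top_k_common_drugs(table, "total", k=100)
        assert common[("ad", "pd")] == {"a"}
        assert any("using all" in r.message for r in caplog.records)

    def test_every_common_drug_in_each_top_k(self) -> None:
        rng = np.random.default_rng(7)
        diseases = {f"dis{j}": {f"drug{i:02d}": float(rng.random()) for i in range(30)} for j in range(3)}
        table = make_table(diseases)
        k = 10
        common = top_k_common_drugs(table, "total", k=k)
        tops = {
            d: set(table.disease_ranking(d)["drug"].head(k))
            for d in diseases
        }
        for subset, drugs in common.items():
            for d in subset:
                assert drugs <= tops[d]


class TestFrequencyConcordance:
    def test_identity_fit(self) -> None:
        freqs = {"a": 0.2, "b": 0.5, "c": 1.0}
        slope, intercept, r2, n = frequency_concordance(freqs, dict(freqs))
        assert (slope, intercept, r2, n) == pytest.approx((1.0, 0.0, 1.0, 3))

    def test_exact_linear_map(self) -> None:
        freqs = {"a": 0.2, "b": 0.5, "c": 1.0}
        doubled = {k: 2 * v for k, v in freqs.items()}
        slope, intercept, r2, _ = frequency_concordance(freqs, doubled)
        assert (slope, intercept, r2) == pytest.approx((2.0, 0.0, 1.0))

    def test_matches_normal_equation_oracle(self) -> None:
        x = {"a": 0.1, "b": 0.4, "c": 0.6, "d": 1.0}
        y = {"a": 0.3, "b": 0.2, "c": 0.9, "d": 0.7}
        slope, intercept, r2, n = frequency_concordance(x, y)
        xv = np.array([x[k] for k in sorted(x)])
        yv = np.array([y[k] for k in sorted(y)])
        design = np.column_stack([xv, np.ones(4)])
        beta = np.linalg.solve(design.T @ design, design.T @ yv)
        residual = yv - design @ beta
        expected_r2 = 1 - residual @ residual / ((yv - yv.mean()) @ (yv - yv.mean()))
        assert slope == pytest.approx(beta[0], abs=1e-12)
        assert intercept == pytest.approx(beta[1], abs=1e-12)
        assert r2 == pytest.approx(expected_r2, abs=1e-12)

    def test_too_few_or_constant_rejected(self) -> None:
        with pytest.raises(UndefinedResultError):
            frequency_concordance({"a": 1.0, "b": 0.5}, {"a": 1.0, "b": 0.5})
        constant = {"a": 0.5, "b": 0.5, "c": 0.5}
        with pytest.raises(UndefinedResultError):
            frequency_concordance(constant, {"a": 0.1, "b": 0.2, "c": 0.3})


def signed_rank_enumeration_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    magnitudes = np.abs(diffs)
    ranks = pd.Series(magnitudes).rank().to_numpy()
    observed = ranks[diffs > 0].sum()
    total = ranks.sum()
    stats = [
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=len(diffs))
    ]
    n_total = len(stats)
    p_low = sum(s <= observed for s in stats) / n_total
    p_high = sum(s >= observed for s in stats) / n_total
    return min(1.0, 2 * min(p_low, p_high))


def rank_sum_enumeration_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n_a = len(a)
    observed = ranks[:n_a].sum()
    stats = [sum(ranks[i] for i in combo) for combo in itertools.combinations(range(len(pooled)), n_a)]
    n_total = len(stats)
    p_low = sum(s <= observed for s in stats) / n_total
    p_high = sum(s >= observed for s in stats) / n_total
    return min(1.0, 2 * min(p_low, p_high))


class TestCompareScoreGroups:
    def test_paired_constant_shift_exact_p(self) -> None:
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        b = a + 0.05
        out = compare_score_groups(a, b, paired=True)
        assert out.method == "exact"
        assert out.p_value == pytest.approx(2 / 2**8, abs=1e-12)
        assert out.p_value == pytest.approx(signed_rank_enumeration_p(b - a), abs=1e-12)

    def test_paired_matches_enumeration_on_mixed_signs(self) -> None:
        rng = np.random.default_rng(11)
        for _ in range(5):
            d = rng.normal(0.1, 0.3, size=9)
            out = compare_score_groups(np.zeros_like(d), d, paired=True)
            assert out.p_value == pytest.approx(signed_rank_enumeration_p(d), abs=1e-12)

    def test_all_zero_differences_degenerate(self) -> None:
        a = np.array([0.1, 0.2, 0.3])
        with pytest.raises(DegenerateTestError):
            compare_score_groups(a, a.copy(), paired=True)

    def test_paired_length_mismatch_rejected(self) -> None:
        with pytest.raises(DomainError):
            compare_score_groups([0.1, 0.2], [0.1], paired=True)

    def test_unpaired_identical_distributions_null_statistic(self) -> None:
        a = np.array([0.1, 0.3, 0.5, 0.7])
        out = compare_score_groups(a, a.copy(), paired=False)
        # U statistic at its null mean n_a*n_b/2
        assert out.statistic == pytest.approx(len(a) * len(a) / 2)

    def test_rank_sum_exact_matches_enumeration(self) -> None:
        rng = np.random.default_rng(23)
        for _ in range(5):
            a = rng.random(5)
            b = rng.random(7) + 0.2
            out = compare_score_groups(a, b, paired=False)
            assert out.method == "exact"
            assert out.p_value == pytest.approx(rank_sum_enumeration_p(a, b), abs=1e-12)

    def test_large_samples_use_approximation(self) -> None:
        rng = np.random.default_rng(5)
        a = rng.random(40)
        b = rng.random(40) + 0.1
        assert compare_score_groups(a, b, paired=True).method == "approx"
        assert compare_score_groups(a, b, paired=False).method == "approx"
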