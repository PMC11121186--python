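"""Synthetic fixture generator: determinism, config contracts, planted
enrichment behaviour, recovery metrics, file round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from dreamocracy.annotations import assign_pathways, load_annotation_table, load_gene_sets, write_annotation_table
from dreamocracy.dcmatrix import build_dc_matrix
from dreamocracy.errors import ConfigError
from dreamocracy.ingestion import build_cts_lists, load_trials_csv, parse_drug_list, resolve_collection
from dreamocracy.synthetic import (
    SimulationConfig,
    generate_collections,
    generate_library,
    recovery_metrics,
    simulate,
    write_fixture_files,
)

SMALL = SimulationConfig(
    n_drugs=60, n_moas=12, n_inds=10, n_pathways=8, n_genes=60, genes_per_pathway=10,
    n_lists=4, list_size=15, n_planted=3, enrichment=5.0, seed=42,
    methods=("CDRS", "CTS"),
)


class TestDeterminism:
    def test_same_seed_identical_library(self, tmp_path) -> None:
        paths = []
        for i in range(2):
            library, _ = generate_library(SMALL)
            path = tmp_path / f"lib{i}.tsv"
            write_annotation_table(library, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_same_seed_identical_collections(self) -> None:
        _, _, cols_a, truth_a = simulate(SMALL)
        _, _, cols_b, truth_b = simulate(SMALL)
        assert truth_a == truth_b
        assert cols_a == cols_b

    def test_different_seed_differs(self) -> None:
        from dataclasses import replace

        _, _, cols_a, _ = simulate(SMALL)
        _, _, cols_b, _ = simulate(replace(SMALL, seed=43))
        assert cols_a != cols_b


class TestConfigContracts:
    def test_fixed_per_drug_counts(self) -> None:
        library, _ = generate_library(SMALL)
        assert all(len(d.moas) == 2 for d in library.drugs.values())
        assert all(len(d.targets) == 3 for d in library.drugs.values())

    def test_ranged_per_drug_counts(self) -> None:
        from dataclasses import replace

        config = replace(SMALL, moas_per_drug=(1, 3))
        library, _ = generate_library(config)
        sizes = {len(d.moas) for d in library.drugs.values()}
        assert sizes <= {1, 2, 3} and len(sizes) > 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"list_size": 100, "n_drugs": 50},
            {"enrichment": 0.5},
            {"moas_per_drug": 20, "n_moas": 12},
            {"n_lists": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs) -> None:
        base = dict(n_drugs=50, n_moas=12, n_inds=5, n_pathways=5, n_genes=40, genes_per_pathway=8)
        base.update(kwargs)
        with pytest.raises(ConfigError):
            config = SimulationConfig(**base)
            generate_library(config)

    def test_explicit_planted_labels_must_exist(self) -> None:
        from dataclasses import replace

        config = replace(SMALL, planted={("disease-a", "MoA"): ("moa-999",)})
        library, _ = generate_library(config)
        with pytest.raises(ConfigError):
            generate_collections(library, config)

    def test_pathways_consistent_with_assign_pathways(self) -> None:
        library, gene_sets = generate_library(SMALL)
        reassigned = assign_pathways(library, gene_sets)
        assert reassigned.drugs == library.drugs


class TestPlantedEnrichment:
    def test_no_signal_matches_library_carrier_rate(self) -> None:
        """Under m=1 carrier frequency in lists tracks the library rate."""
        from dataclasses import replace

        config = replace(SMALL, enrichment=1.0, methods=("CDRS",))
        in_list_fracs = []
        carrier_fracs = []
        for seed in range(40):
            library, _, = generate_library(replace(config, seed=seed))
            collections, truth = generate_collections(library, replace(config, seed=seed))
            carriers = truth.carriers["disease-a"]
            carrier_fracs.append(len(carriers) / len(library))
            for lst in collections[("disease-a", "CDRS")].lists:
                in_list_fracs.append(len(lst.drugs & carriers) / len(lst.drugs))
        # Null: mean in-list fraction == mean carrier fraction, up to MC error
        assert np.mean(in_list_fracs) == pytest.approx(np.mean(carrier_fracs), abs=0.03)

    def test_extreme_enrichment_fills_lists_with_carriers(self) -> None:
        from dataclasses import replace

        config = replace(SMALL, enrichment=200.0, n_planted=6, methods=("CDRS",))
        library, _ = generate_library(config)
        collections, truth = generate_collections(library, config)
        carriers = truth.carriers["disease-a"]
        assert len(carriers) >= config.list_size  # enough carriers to fill a list
        for lst in collections[("disease-a", "CDRS")].lists:
            assert len(lst.drugs & carriers) / len(lst.drugs) > 0.9

    def test_planted_features_rank_high_under_enrichment(self) -> None:
        library, _, collections, truth = simulate(SimulationConfig(seed=7))
        matrix = build_dc_matrix(collections[("disease-a", "CDRS")], library, modalities=("MoA",))
        planted = truth.planted[("disease-a", "CDRS", "MoA")]
        ranked = list(matrix.entries["feature"])
        planted_ranks = [ranked.index(f) for f in planted]
        other_ranks = [i for i, f in enumerate(ranked) if f not in planted]
        assert np.median(planted_ranks) < np.median(other_ranks)


class TestRecoveryMetrics:
    def matrix_and_truth(self):
        library, _, collections, truth = simulate(SimulationConfig(seed=3))
        matrix = build_dc_matrix(collections[("disease-a", "CDRS")], library, modalities=("MoA",))
        return matrix, truth

    def test_perfect_recovery(self) -> None:
        matrix, truth = self.matrix_and_truth()
        metrics = recovery_metrics(matrix, truth, top_j=5)["MoA"]
        assert metrics.precision == 1.0 and metrics.recall == 1.0

    def test_degenerate_empty_kept(self) -> None:
        matrix, truth = self.matrix_and_truth()
        # an alpha of 0 empties the kept table (p-values are never negative)
        from dreamocracy.dcmatrix import DCMatrix, filter_matrix

        empty = DCMatrix(
            disease=matrix.disease,
            method=matrix.method,
            weights=matrix.weights,
            alpha=0.0,
            entries=filter_matrix(matrix.entries, alpha=0.0),
        )
        metrics = recovery_metrics(empty, truth, top_j=5)["MoA"]
        assert metrics.degenerate and metrics.precision == 0.0 and metrics.recall == 0.0

    def test_top_j_clamped(self, caplog) -> None:
        matrix, truth = self.matrix_and_truth()
        n_kept = len(matrix.modality_entries("MoA", kept_only=True))
        with caplog.at_level("WARNING"):
            metrics = recovery_metrics(matrix, truth, top_j=n_kept + 50)["MoA"]
        assert metrics.top_j == n_kept


class TestFixtureFiles:
    def test_round_trip_through_real_readers(self, tmp_path) -> None:
        library, gene_sets, collections, truth = simulate(SMALL)
        manifest = write_fixture_files(library, gene_sets, collections, truth, tmp_path)

        reloaded = load_annotation_table(manifest["library"], dialect="hub")
        reloaded = assign_pathways(reloaded, load_gene_sets(manifest["gene_sets"]))
        assert reloaded == library

        # CDRS lists parse back to the generated drug sets
        for disease, paths in manifest["cdrs_lists"].items():
            generated = {lst.list_id: lst.drugs for lst in collections[(disease, "CDRS")].lists}
            for path in paths:
                lst = parse_drug_list(path, disease=disease)
                assert lst.drugs == generated[lst.list_id]

    def test_cts_decoys_are_filtered_out(self, tmp_path) -> None:
        library, gene_sets, collections, truth = simulate(SMALL)
        manifest = write_fixture_files(library, gene_sets, collections, truth, tmp_path)
        for disease, path in manifest["cts_trials"].items():
            records = load_trials_csv(path)
            assert any(r.status == "Terminated" for r in records)  # decoy present in the file
            lists = build_cts_lists(records, disease=disease)
            terminated_ids = {r.trial_id for r in records if r.status == "Terminated"}
            assert terminated_ids.isdisjoint({lst.list_id for lst in lists})
            collection = resolve_collection(lists, library)
            assert collection.drug_union() <= frozenset(library.drugs)
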