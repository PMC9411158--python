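"""Readers, writers, round trips and input validation."""

import numpy as np
import pandas as pd
import pytest

from comorbnet import PipelineConfig
from comorbnet.core_io import (
    DrugIndicationScoreMatrix,
    DrugTargetMap,
    ProteinUniverse,
    load_gene_list,
    load_world,
    rank_edges,
    read_clinical,
    read_edge_table,
    read_gmt,
    read_score_matrix,
    read_target_map,
    write_edge_table,
    write_score_matrix,
    write_target_map,
)
from comorbnet.exceptions import LoadError, ParseError, ValidationError
from comorbnet.synth import write_bundle

from conftest import make_edges


class TestScoreMatrixRoundTrip:
    def test_three_drug_two_indication_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            [[0.1, -2.5], [1e-300, 3.0], [1000.0, 0.0]],
            index=["d1", "d2", "d3"],
            columns=["ind1", "ind2"],
        )
        path = tmp_path / "scores.tsv"
        write_score_matrix(DrugIndicationScoreMatrix(frame), path)
        back = read_score_matrix(path)
        assert back.drugs == ["d1", "d2", "d3"]
        assert back.indications == ["ind1", "ind2"]
        assert np.array_equal(back.frame.to_numpy(), frame.to_numpy())

    def test_malformed_cell_reports_line(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("drug\tind1\nd1\t0.5\nd2\toops\n")
        with pytest.raises(ParseError, match="line 3"):
            read_score_matrix(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(LoadError, match="nope.tsv"):
            read_score_matrix(tmp_path / "nope.tsv")


class TestTargetMap:
    def test_round_trip(self, tmp_path):
        targets = DrugTargetMap({"d1": frozenset({"A", "B"}), "d2": frozenset({"B"})})
        path = tmp_path / "targets.tsv"
        write_target_map(targets, path)
        back = read_target_map(path)
        assert back.targets == targets.targets

    def test_unknown_protein_rejected(self):
        universe = ProteinUniverse(["A", "B"])
        targets = DrugTargetMap({"d1": frozenset({"A", "ZZZ"})})
        with pytest.raises(ValidationError, match="ZZZ"):
            targets.validate(universe, ["d1"])


class TestEdgeTable:
    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_table(make_edges([]), path)
        assert path.read_text().splitlines() == [
            "disease_a\tdisease_b\tn_shared\tj_score\tp_value\tq_value"
        ]

    def test_single_edge_two_lines(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_table(make_edges([("a", "b", 2, 0.5, 0.0222, 0.0222, True)]), path)
        assert len(path.read_text().splitlines()) == 2

    def test_tied_q_ordered_by_j_then_pair(self):
        edges = make_edges(
            [
                ("x", "y", 1, 0.2, 0.01, 0.05, True),
                ("a", "b", 1, 0.9, 0.01, 0.05, True),
                ("a", "c", 1, 0.2, 0.01, 0.05, True),
            ]
        )
        ranked = rank_edges(edges)
        assert list(zip(ranked["disease_a"], ranked["disease_b"])) == [
            ("a", "b"),
            ("a", "c"),
            ("x", "y"),
        ]

    def test_round_trip_full_precision(self, tmp_path):
        values = [1e-300, 2.3e-17, 0.4999999999999, 1.0, 1e3]
        edges = make_edges(
            [(f"d{i}", f"e{i}", i, v if v <= 1 else 0.5, min(v, 1.0), min(v, 1.0), False)
             for i, v in enumerate(values)]
        )
        path = tmp_path / "edges.tsv"
        write_edge_table(edges, path)
        back = read_edge_table(path)
        merged = back.merge(rank_edges(edges), on=["disease_a", "disease_b"], suffixes=("", "_orig"))
        for col in ("j_score", "p_value", "q_value"):
            np.testing.assert_allclose(merged[col], merged[f"{col}_orig"], rtol=1e-12)


class TestGMT:
    def test_two_field_line_is_parse_error(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("ok\tdesc\tG1\tG2\nbroken\tdesc-only\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gmt(path)

    def test_round_trip_via_bundle(self, tmp_path, small_world):
        paths = write_bundle(small_world, tmp_path)
        collection = read_gmt(paths["gmt"])
        assert set(collection) == set(small_world.inputs.gene_sets)
        for name in collection:
            assert collection.genes_of(name) == small_world.inputs.gene_sets.genes_of(name)


class TestClinical:
    def test_nab_exceeding_margin_rejected(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("disease_a\tdisease_b\tn_a\tn_b\tn_ab\nx\ty\t10\t5\t7\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_clinical(path)

    def test_malformed_count_reports_line(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text(
            "disease_a\tdisease_b\tn_a\tn_b\tn_ab\nx\ty\t10\t5\t2\nx\tz\t10\tbad\t2\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_clinical(path)


class TestGeneList:
    def test_deduplicates(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("A\nB\nA\n")
        assert load_gene_list(path).genes == {"A", "B"}

    def test_blank_only_file_raises(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("\n\n  \n")
        with pytest.raises(LoadError, match="no usable"):
            load_gene_list(path)

    def test_unknown_identifiers_counted_not_fatal(self, tmp_path):
        universe = ProteinUniverse([f"G{i}" for i in range(200)])
        lines = [f"G{i}" for i in range(152)] + ["NOPE1", "NOPE2", "NOPE3"]
        path = tmp_path / "genes.txt"
        path.write_text("\n".join(lines) + "\n")
        result = load_gene_list(path, universe)
        assert len(result.genes) == 152
        assert result.n_unknown == 3


class TestWorldBundle:
    def test_generated_bundle_survives_load_world(self, tmp_path, small_world):
        paths = write_bundle(small_world, tmp_path)
        config = PipelineConfig(clinical_n_tot=small_world.truth.params.clinical_n_tot)
        world = load_world(paths, config)
        orig = small_world.inputs
        assert world.universe.proteins == orig.universe.proteins
        assert world.scores.drugs == orig.scores.drugs
        np.testing.assert_allclose(
            world.scores.frame.to_numpy(), orig.scores.frame.to_numpy(), rtol=1e-15
        )
        assert world.targets.targets == dict(orig.targets.targets)
        pd.testing.assert_frame_equal(
            world.clinical.reset_index(drop=True), orig.clinical.reset_index(drop=True)
        )

    def test_required_key_missing(self):
        with pytest.raises(LoadError, match="scores"):
            load_world({"universe": "u.txt", "targets": "t.tsv"}, PipelineConfig())


class TestPipelineConfig:
    def test_defaults_are_the_published_operating_point(self):
        cfg = PipelineConfig()
        assert cfg.z_cutoff == 1.65
        assert cfg.moa_p_cutoff == 0.05
        assert cfg.alpha == 0.025
        assert cfg.top_k_comorbid == 100
        assert cfg.enrich_score_cutoff == 0.01
        assert cfg.easy_pair_cutoff == 0.9
        assert cfg.n_permutations == 100

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            PipelineConfig(pair_q_cutoff=1.5)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = PipelineConfig(z_cutoff=2.0, rng_seed=9, clinical_n_tot=1000)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert PipelineConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("zz_cutoff: 1.0\n")
        with pytest.raises(ParseError, match="zz_cutoff"):
            PipelineConfig.from_yaml(path)
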