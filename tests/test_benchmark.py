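"""Clinical statistics, evaluation metrics and permutation nulls."""

import math

import numpy as np
import pandas as pd
import pytest

from comorbnet import PipelineConfig
from comorbnet.benchmark import (
    auroc,
    evaluate,
    log_rr,
    permutation_test,
    permute_drug_disease,
    permute_drug_protein,
    phi_score,
)
from comorbnet.core_io import DrugIndicationScoreMatrix, DrugTargetMap
from comorbnet.exceptions import DomainError, ValidationError

from conftest import make_edges


class TestLogRR:
    def test_independence_is_zero(self):
        # n_ab = n_a * n_b / n_tot exactly
        assert log_rr(100, 200, 20, 1000) == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_enrichment(self):
        assert log_rr(10, 10, 10, 100) == pytest.approx(math.log(10), rel=1e-12)

    def test_zero_overlap_undefined(self):
        with pytest.raises(DomainError):
            log_rr(10, 10, 0, 100)


class TestPhiScore:
    def test_independence_is_zero(self):
        assert phi_score(100, 200, 20, 1000) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_cooccurrence(self):
        assert phi_score(50, 50, 50, 100) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # (10*100 - 20*30) / sqrt(20*30*80*70)
        assert phi_score(20, 30, 10, 100) == pytest.approx(400 / math.sqrt(3_360_000))

    def test_degenerate_margin_raises(self):
        with pytest.raises(DomainError):
            phi_score(0, 30, 0, 100)

    def test_sign_agrees_with_log_rr_on_sweep(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 1000:
            n_tot = int(rng.integers(50, 10_000))
            n_a = int(rng.integers(1, n_tot))
            n_b = int(rng.integers(1, n_tot))
            n_ab = int(rng.integers(1, min(n_a, n_b) + 1))
            if n_ab < max(0, n_a + n_b - n_tot):
                continue
            assert np.sign(phi_score(n_a, n_b, n_ab, n_tot)) == np.sign(
                log_rr(n_a, n_b, n_ab, n_tot)
            )
            checked += 1


class TestAuroc:
    def test_perfect_ordering(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_score_is_half(self):
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_example(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(20, 200))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            assert auroc(scores, labels) == pytest.approx(cmp.mean(), rel=1e-12)


def _bench_tables(n_pairs=20, seed=0):
    """Predicted edges and clinical counts with J tracking the label."""
    rng = np.random.default_rng(seed)
    edge_rows, clin_rows = [], []
    n_tot = 10_000
    for i in range(n_pairs):
        a, b = f"d{i:02d}", f"e{i:02d}"
        positive = i % 2 == 0
        n_a, n_b = int(rng.integers(100, 500)), int(rng.integers(100, 500))
        indep = n_a * n_b / n_tot
        n_ab = int(max(1, indep * (3.0 if positive else 0.3)))
        j = (0.5 if positive else 0.05) + rng.uniform(0, 0.01)
        q = 0.001 if positive else 0.5
        edge_rows.append((a, b, 1, j, q, q, positive))
        clin_rows.append((a, b, n_a, n_b, n_ab))
    edges = make_edges(edge_rows)
    clinical = pd.DataFrame(
        clin_rows, columns=["disease_a", "disease_b", "n_a", "n_b", "n_ab"]
    )
    return edges, clinical, PipelineConfig(clinical_n_tot=n_tot)


class TestEvaluate:
    def test_metrics_on_separable_tables(self):
        edges, clinical, config = _bench_tables()
        report = evaluate(edges, clinical, config)
        assert report.recall == pytest.approx(100.0)
        assert report.precision == pytest.approx(100.0)
        assert report.auroc == pytest.approx(1.0)
        assert report.cc_logrr > 0.8
        assert report.n_pairs_used == 20

    def test_easy_pairs_excluded_exactly(self):
        edges, clinical, config = _bench_tables()
        eff = {d: frozenset({"drg1", "drg2"}) for d in edges["disease_a"]}
        eff.update(
            {d: frozenset({"drg1", "drg2"}) for d in edges["disease_b"].iloc[:4]}
        )
        # remaining diseases get disjoint drug sets -> easy score 0
        for d in edges["disease_b"].iloc[4:]:
            eff[d] = frozenset({"other1", "other2"})
        report = evaluate(edges, clinical, config, eff_sets=eff)
        assert report.n_excluded_easy == 4
        assert report.n_pairs_used == 16

    def test_no_overlap_raises(self):
        edges, clinical, config = _bench_tables()
        clinical["disease_a"] = "zz" + clinical["disease_a"]
        with pytest.raises(ValidationError, match="no overlapping pairs"):
            evaluate(edges, clinical, config)

    def test_too_few_pairs_raises(self):
        edges, clinical, config = _bench_tables(n_pairs=5)
        with pytest.raises(ValidationError, match=">= 10"):
            evaluate(edges, clinical, config)

    def test_missing_n_tot_raises(self):
        edges, clinical, _ = _bench_tables()
        with pytest.raises(ValidationError, match="clinical_n_tot"):
            evaluate(edges, clinical, PipelineConfig())


class TestPermutations:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.drugs = [f"d{i}" for i in range(10)]
        self.targets = DrugTargetMap(
            {d: frozenset({f"P{i}", f"P{i + 1}"}) for i, d in enumerate(self.drugs)}
        )
        self.scores = DrugIndicationScoreMatrix(
            pd.DataFrame(
                rng.normal(size=(10, 3)), index=self.drugs, columns=["i1", "i2", "i3"]
            )
        )

    def test_drug_protein_deterministic_and_conserving(self):
        a = permute_drug_protein(self.targets, self.drugs, seed=5)
        b = permute_drug_protein(self.targets, self.drugs, seed=5)
        assert a.targets == b.targets
        before = sorted(map(sorted, self.targets.targets.values()))
        after = sorted(map(sorted, a.targets.values()))
        assert before == after

    def test_drug_disease_deterministic_and_conserving(self):
        a = permute_drug_disease(self.scores, seed=5)
        b = permute_drug_disease(self.scores, seed=5)
        assert a.frame.equals(b.frame)
        before = sorted(map(tuple, self.scores.frame.to_numpy().tolist()))
        after = sorted(map(tuple, a.frame.to_numpy().tolist()))
        assert before == after

    def test_two_drug_map_realizes_both_outcomes(self):
        targets = DrugTargetMap({"d1": frozenset({"A"}), "d2": frozenset({"B"})})
        outcomes = set()
        for seed in range(20):
            out = permute_drug_protein(targets, ["d1", "d2"], seed)
            outcomes.add(tuple(sorted(out.targets_of("d1"))))
        assert outcomes == {("A",), ("B",)}

    def test_single_drug_raises(self):
        with pytest.raises(ValidationError):
            permute_drug_protein(DrugTargetMap({"d": frozenset()}), ["d"], 0)


class TestPermutationTest:
    def test_small_null_destroys_planted_signal(self, default_world):
        inputs = default_world.inputs
        config = inputs.config.with_overrides(n_permutations=5)
        summaries = permutation_test(inputs, inputs.clinical, config, "drug_disease")
        by_name = {s.metric: s for s in summaries}
        assert set(by_name) == {
            "cc_logrr", "cc_phi", "recall", "precision", "auroc", "auprc"
        }
        s = by_name["cc_logrr"]
        assert s.observed > s.null_mean
        assert s.z > 0 and 0 <= s.p < 0.5

    def test_unknown_kind_rejected(self, small_world):
        with pytest.raises(ValidationError):
            permutation_test(
                small_world.inputs,
                small_world.inputs.clinical,
                small_world.inputs.config,
                "nope",
            )

    def test_sparse_null_leaves_undefined_metrics_as_nan(self, small_world):
        """A tiny world's null runs often have no defined correlation; the
        summary must report nan rather than fail."""
        inputs = small_world.inputs
        config = inputs.config.with_overrides(n_permutations=3)
        summaries = permutation_test(inputs, inputs.clinical, config, "drug_protein")
        assert len(summaries) == 6  # one per metric, even when z is undefined
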