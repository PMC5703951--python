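"""Edge-deletion CV, confidence binning, random-model null, benchmarks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from adrkg import (
    AdrModel,
    CvReport,
    KnowledgeGraph,
    ObservationTable,
    PlantedSpec,
    PredictorSet,
    assign_confidence,
    build_feature_matrix,
    edge_deletion_cv,
    expected_random_recovery,
    generate_graph,
    random_model_significance,
    select_predictors,
    train_benchmarks,
)
from adrkg.enrich import ContingencyTable, EnrichmentResult
from adrkg.evaluate import EvaluationError
from adrkg.model import ModelError

from conftest import A, D, I, T


class TestExpectedRandomRecovery:
    def test_boundary_values(self):
        assert expected_random_recovery(0, 7) == 0.0
        assert expected_random_recovery(7, 7) == 1.0

    def test_matches_exhaustive_enumeration(self):
        """E[fraction of 3 deleted drugs hit by 2 random picks from 10] over all C(10,2) draws."""
        deleted = {0, 1, 2}
        fractions = [
            len(set(pick) & deleted) / len(deleted)
            for pick in itertools.combinations(range(10), 2)
        ]
        assert expected_random_recovery(2, 10) == pytest.approx(np.mean(fractions))
        assert expected_random_recovery(2, 10) == pytest.approx(0.2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(EvaluationError):
            expected_random_recovery(1, 0)
        with pytest.raises(EvaluationError):
            expected_random_recovery(5, 3)


class TestAssignConfidence:
    def _report(self, raw, n_success=10):
        folds = [
            type("F", (), {"trained": True})() for _ in range(n_success)
        ]
        r = CvReport(A("a"), [], None, None, raw)
        r.folds = folds
        return r

    def test_binning_rule(self):
        rs = [self._report(x) for x in (5.0, 2.0, 0.8)]
        assign_confidence(rs)
        assert [r.confidence_bin for r in rs] == ["high", "mid", "low"]

    def test_all_equal_ratios_none_high(self):
        rs = [self._report(2.0) for _ in range(4)]
        assign_confidence(rs)
        assert all(r.confidence_bin == "mid" for r in rs)

    def test_too_few_successful_folds_forces_low(self):
        rs = [self._report(9.0, n_success=5), self._report(3.0), self._report(2.0)]
        assign_confidence(rs)
        assert rs[0].confidence_bin == "low"
        # the 5-fold ADR is excluded from the median, so 3.0 > median(3, 2) is not high
        assert rs[1].confidence_bin in {"high", "mid"}


def _toy_validation_setup(M, K, N, V):
    """Graph with 1 cause + M eligible non-causes; a model whose new
    predictions are exactly N chosen pool drugs, V of them observed."""
    adr = A("a*")
    marker = T("t*")
    g = KnowledgeGraph()
    cause = D("cause")
    g.add_edge(cause, adr)
    g.add_edge(cause, marker)
    pool = [D(f"p{i}") for i in range(M)]
    preds = pool[:N]
    for d in pool:
        g.add_edge(d, T("t_bg"))  # ensures presence in graph
    for d in preds:
        g.add_edge(d, marker)
    result = EnrichmentResult(marker, "target", ContingencyTable(1, 0, N, M - N), 0.01, 0.01)
    ps = PredictorSet(adr, {"target": [result]})
    model = AdrModel(
        adr=adr,
        predictor_set=ps,
        feature_types=["target"],
        w=np.array([1.0]),
        threshold=0.5,
        j=1.0,
        scaling_params=[(0.0, 1.0)],
        scores={},
    )
    # exactly K observed drugs in the M-drug pool, V of them among the predictions
    assert M >= N + (K - V)
    observed = {d.identifier for d in preds[:V]} | {d.identifier for d in pool[N : N + K - V]}
    rows = [
        {"drug_id": d.identifier, "adr_id": adr.identifier, "observed": d.identifier in observed}
        for d in pool
    ]
    obs = ObservationTable(pd.DataFrame(rows))
    return model, g, obs


class TestRandomModelSignificance:
    def test_zero_validated_gives_p_one(self):
        model, g, obs = _toy_validation_setup(M=12, K=4, N=3, V=0)
        rep = random_model_significance(model, g, obs, n_iter=2000, seed=5)
        assert rep.n_validated == 0
        assert rep.p_random == pytest.approx(1.0)

    def test_small_case_matches_exact_tail(self):
        # M=10, K=5, N=2, V=2: P = C(5,2)/C(10,2) = 10/45
        model, g, obs = _toy_validation_setup(M=10, K=5, N=2, V=2)
        rep = random_model_significance(model, g, obs, n_iter=100_000, seed=11)
        exact = 10 / 45
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert rep.n_predictions == 2 and rep.n_validated == 2
        assert rep.expected_validated == pytest.approx(2 * 5 / 10)
        assert abs(rep.p_random - exact) < 3 * se

    def test_reported_significance_threshold(self):
        model, g, obs = _toy_validation_setup(M=40, K=4, N=4, V=4)
        rep = random_model_significance(model, g, obs, n_iter=50_000, seed=3)
        assert rep.significant == (rep.p_random < 0.05)
        assert rep.significant

    def test_no_predictions_outcome(self):
        model, g, obs = _toy_validation_setup(M=8, K=2, N=0, V=0)
        rep = random_model_significance(model, g, obs, n_iter=1000, seed=0)
        assert rep.n_predictions == 0
        assert rep.p_random is None and not rep.significant

    @pytest.mark.parametrize("M,K,N,V", [(20, 6, 5, 3), (30, 10, 4, 2), (15, 3, 5, 1)])
    def test_monte_carlo_matches_hypergeometric_tail(self, M, K, N, V):
        model, g, obs = _toy_validation_setup(M, K, N, V)
        rep = random_model_significance(model, g, obs, n_iter=100_000, seed=17)
        exact = float(hypergeom.sf(V - 1, M, K, N))
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(rep.p_random - exact) <= 3 * se + 1e-12


class TestEdgeDeletionCv:
    def test_reproducible_with_fixed_seed(self, strong_graph):
        g, truth = strong_graph
        r1 = edge_deletion_cv(g, truth.target_adr, k=5, seed=42)
        r2 = edge_deletion_cv(g, truth.target_adr, k=5, seed=42)
        assert [f.deleted_drugs for f in r1.folds] == [f.deleted_drugs for f in r2.folds]
        assert r1.mean_recovery == r2.mean_recovery

    def test_graph_unchanged_after_cv(self, strong_graph):
        g, truth = strong_graph
        before = sorted(g.edges())
        edge_deletion_cv(g, truth.target_adr, k=5, seed=0)
        assert sorted(g.edges()) == before

    def test_folds_partition_the_causes(self, strong_graph):
        g, truth = strong_graph
        causes = g.neighbors(truth.target_adr)
        report = edge_deletion_cv(g, truth.target_adr, k=5, seed=1)
        seen = [d for f in report.folds for d in f.deleted_drugs]
        assert len(seen) == len(causes)
        assert set(seen) == causes

    def test_recovery_beats_random_on_planted_signal(self, strong_graph):
        g, truth = strong_graph
        report = edge_deletion_cv(g, truth.target_adr, k=5, seed=3)
        assert report.mean_recovery is not None
        assert report.mean_recovery > report.expected_random_recovery
        assert report.raw_confidence > 1

    def test_unique_shared_target_recovered_perfectly(self):
        """Causes share a target no one else has: deletion preserves the signal."""
        g = KnowledgeGraph()
        adr = A("a1")
        for i in range(10):
            d = D(f"c{i}")
            g.add_edge(d, adr)
            g.add_edge(d, T("t_shared"))
            g.add_edge(d, I("i_shared"))
            g.add_edge(d, A("a_shared"))
        for i in range(30):
            d = D(f"o{i}")
            g.add_edge(d, T(f"t{i % 5}"))
            g.add_edge(d, I("i_other"))
            g.add_edge(d, A("a_other"))
        report = edge_deletion_cv(g, adr, k=5, seed=0)
        assert report.mean_recovery == pytest.approx(1.0)

    def test_k_below_two_rejected(self, strong_graph):
        g, truth = strong_graph
        with pytest.raises(EvaluationError):
            edge_deletion_cv(g, truth.target_adr, k=1)


class TestBenchmarks:
    def _separable(self):
        g, truth = generate_graph(PlantedSpec(seed=3, signal_p=1.0, background_p=0.02))
        ps = select_predictors(g, truth.target_adr)
        Dm = build_feature_matrix(g, ps)
        labels = np.array([g.has_edge(d, truth.target_adr) for d in Dm.drugs])
        return Dm, labels

    @pytest.mark.parametrize("method", ["LR", "DT", "SVM"])
    def test_separable_case_recovered(self, method):
        Dm, labels = self._separable()
        clf, new = train_benchmarks(Dm, labels, method)
        pred = clf.predict(Dm.values).astype(bool)
        assert (pred == labels).mean() > 0.95
        # new predictions are exactly the training-set false positives
        assert new == {d for d, p, y in zip(Dm.drugs, pred, labels) if p and not y}

    def test_degenerate_labels_rejected(self):
        Dm, labels = self._separable()
        with pytest.raises(ModelError):
            train_benchmarks(Dm, np.ones_like(labels), "LR")

    def test_unknown_method_rejected(self):
        Dm, labels = self._separable()
        with pytest.raises(EvaluationError):
            train_benchmarks(Dm, labels, "RF")

    def test_benchmark_cv_runs(self, strong_graph):
        g, truth = strong_graph
        report = edge_deletion_cv(g, truth.target_adr, k=3, seed=0, method="DT")
        assert report.n_successful >= 1


class TestObservationTable:
    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"drug_id": ["d1", "d2"], "adr_id": ["a1", "a1"], "observed": [True, False]}
        )
        obs = ObservationTable(df)
        p = tmp_path / "obs.tsv"
        obs.save(p)
        back = ObservationTable.load(p)
        assert back.eligible_drugs(A("a1")) == {"d1", "d2"}
        assert back.observed_drugs(A("a1")) == {"d1"}

    def test_duplicate_pairs_rejected(self):
        df = pd.DataFrame(
            {"drug_id": ["d1", "d1"], "adr_id": ["a1", "a1"], "observed": [True, False]}
        )
        with pytest.raises(EvaluationError):
            ObservationTable(df)
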