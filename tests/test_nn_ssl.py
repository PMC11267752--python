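"""Soft-label imputation, candidate selection, convergence, the SSL loop."""

import numpy as np
import pytest

from sdpre.classifier import REModel, TrainConfig
from sdpre.nn_ssl import (
    SSLConfig,
    check_convergence,
    compute_soft_label,
    cosine_similarity,
    imputation_bias_report,
    run_ssl,
    select_candidates,
    self_training_iteration,
)
from sdpre.experiments import stub_encoder_for


class TestComputeSoftLabel:
    def test_worked_softmax_example(self):
        # top-2 neighbors: class 0 at similarity 0.9, class 1 at 0.7,
        # class 2 absent -> softmax(0.9, 0.7, 0); cosines engineered by angle
        a = np.arccos(0.9)
        b = a + np.arccos(0.7)
        u = np.array([np.cos(a), np.sin(a)])
        labeled = np.array([[1.0, 0.0], [np.cos(b), np.sin(b)]])
        assert np.isclose(cosine_similarity(u, labeled[0]), 0.9)
        assert np.isclose(cosine_similarity(u, labeled[1]), 0.7)
        soft = compute_soft_label(u, labeled, np.array([0, 1]), n_classes=3, k=2)
        assert np.allclose(soft, [0.4494, 0.3679, 0.1827], atol=1e-4)
        assert np.isclose(soft.sum(), 1.0, atol=1e-9)

    def test_zero_aggregates_uniform(self):
        labeled = np.array([[0.0, 0.0]])  # zero norm -> similarity 0
        soft = compute_soft_label(np.array([1.0, 0.0]), labeled, np.array([0]),
                                  n_classes=4, k=5)
        assert np.allclose(soft, 0.25)

    def test_unanimous_neighbors_win_argmax(self, rng):
        labeled = rng.standard_normal((10, 5)) + 4.0
        classes = np.full(10, 2)
        u = labeled[0] + 0.01
        soft = compute_soft_label(u, labeled, classes, n_classes=4, k=5)
        assert soft.argmax() == 2

    def test_requires_labeled_pool(self):
        with pytest.raises(ValueError):
            compute_soft_label(np.ones(3), np.empty((0, 3)), np.empty(0, int), 2)

    def test_always_normalizes(self, rng):
        for _ in range(50):
            labeled = rng.standard_normal((8, 4))
            soft = compute_soft_label(rng.standard_normal(4), labeled,
                                      rng.integers(0, 3, 8), n_classes=3, k=3)
            assert np.isclose(soft.sum(), 1.0, atol=1e-9)
            assert (soft >= 0).all()


class TestSelectCandidates:
    def test_identical_point_ranked_first(self, rng):
        labeled = rng.standard_normal((5, 4))
        pool = [("far", rng.standard_normal(4) * 0.01 + 10),
                ("clone", labeled[2].copy())]
        assert select_candidates(pool, labeled, m=1, k=1)[0] == "clone"

    def test_m_larger_than_pool(self, rng):
        labeled = rng.standard_normal((3, 4))
        pool = [("a", rng.standard_normal(4)), ("b", rng.standard_normal(4))]
        assert len(select_candidates(pool, labeled, m=10, k=2)) == 2

    def test_matches_brute_force(self, rng):
        labeled = rng.standard_normal((12, 6))
        pool = [(f"u{i:02d}", rng.standard_normal(6)) for i in range(20)]
        k, m = 4, 7
        got = select_candidates(pool, labeled, m=m, k=k)
        scores = {}
        for uid, vec in pool:
            sims = sorted((cosine_similarity(vec, lv) for lv in labeled), reverse=True)
            scores[uid] = np.mean(sims[:k])
        expected = sorted(scores, key=lambda u: (-scores[u], u))[:m]
        assert got == expected


class TestConvergence:
    def test_four_percent_converges(self):
        prev = np.zeros(100)
        cur = prev.copy()
        cur[:4] = 1
        assert check_convergence(prev, cur, 0.05)

    def test_six_percent_does_not(self):
        prev = np.zeros(100)
        cur = prev.copy()
        cur[:6] = 1
        assert not check_convergence(prev, cur, 0.05)

    def test_identical_snapshots_converge(self):
        snap = np.arange(10)
        assert check_convergence(snap, snap, 1e-6)

    def test_empty_monitoring_set_rejected(self):
        with pytest.raises(ValueError):
            check_convergence(np.empty(0), np.empty(0), 0.05)


class TestRunSsl:
    def test_augmented_growth_bound_and_disjointness(self, small_corpus):
        enc = stub_encoder_for(small_corpus)
        cfg = SSLConfig(seed=0, max_iters=4, conv_threshold=0.001, m_impute=5)
        model, state = run_ssl(small_corpus.labeled, small_corpus.unlabeled,
                               small_corpus.schema, "sdp", enc, cfg,
                               TrainConfig.stub_default(seed=0, epochs=60))
        assert len(state.augmented) <= state.iteration * cfg.m_impute
        labeled_ids = {ex.id for ex in small_corpus.labeled}
        aug_ids = [i for i, _ in state.augmented]
        assert len(set(aug_ids)) == len(aug_ids)
        assert not (set(aug_ids) & labeled_ids)
        for _, soft in state.augmented:
            assert np.isclose(soft.sum(), 1.0, atol=1e-9)

    def test_threshold_one_stops_after_first_iteration(self, small_corpus):
        enc = stub_encoder_for(small_corpus)
        cfg = SSLConfig(seed=0, max_iters=8, conv_threshold=1.0)
        _, state = run_ssl(small_corpus.labeled, small_corpus.unlabeled,
                           small_corpus.schema, "sdp", enc, cfg,
                           TrainConfig.stub_default(seed=0, epochs=60))
        assert state.iteration == 1
        assert state.converged

    def test_monitoring_set_never_imputed(self, small_corpus):
        enc = stub_encoder_for(small_corpus)
        cfg = SSLConfig(seed=5, max_iters=6, conv_threshold=0.001, val_fraction=0.2)
        _, state = run_ssl(small_corpus.labeled, small_corpus.unlabeled,
                           small_corpus.schema, "sdp", enc, cfg,
                           TrainConfig.stub_default(seed=5, epochs=60))
        rng = np.random.default_rng(cfg.seed)
        n_val = max(1, int(round(cfg.val_fraction * len(small_corpus.unlabeled))))
        val_idx = rng.choice(len(small_corpus.unlabeled), size=n_val, replace=False)
        val_ids = {small_corpus.unlabeled[int(i)].id for i in val_idx}
        assert not (val_ids & {i for i, _ in state.augmented})

    def test_empty_labeled_pool_rejected(self, small_corpus):
        enc = stub_encoder_for(small_corpus)
        with pytest.raises(ValueError):
            run_ssl([], small_corpus.unlabeled, small_corpus.schema, "sdp", enc)

    def test_log_records_one_per_iteration(self, small_corpus):
        enc = stub_encoder_for(small_corpus)
        cfg = SSLConfig(seed=1, max_iters=3, conv_threshold=0.001)
        _, state = run_ssl(small_corpus.labeled, small_corpus.unlabeled,
                           small_corpus.schema, "sdp", enc, cfg,
                           TrainConfig.stub_default(seed=1, epochs=60))
        assert len(state.log) == state.iteration
        for rec in state.log:
            assert set(rec) >= {"iteration", "imputed_ids", "variation"}


class TestParameterRecovery:
    def test_imputation_accuracy_rises_with_separation(self):
        # planted truth is the oracle: widening the class-signal offset
        # must make nearest-neighbor imputation more accurate
        from sdpre.experiments import ssl_experiment
        from sdpre.synthetic import SynthConfig, generate_corpus

        means = []
        for delta in (0.0, 0.5, 2.0):
            accs = []
            for seed in (0, 1, 2):
                c = generate_corpus(SynthConfig(n_examples=200, labeled_budget=40,
                                                test_size=40, delta=delta, seed=seed))
                res = ssl_experiment(c, "sdp", None, SSLConfig(seed=seed, max_iters=6))
                accs.append(res["audit"]["imputation_accuracy"])
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]


class TestSelfTraining:
    def _model(self, schema, dim=4):
        m = REModel.initialize(schema, "sdp", dim, seed=0)
        m.W[:] = np.eye(len(schema), dim)[:, :dim] * 10
        return m

    def test_cap_truncates(self, schema, rng):
        m = self._model(schema)
        pool = [(f"u{i:03d}", np.eye(4)[i % 4] * 5) for i in range(150)]
        out = self_training_iteration(m, pool, tau=0.9, cap=100)
        assert len(out) == 100

    def test_none_above_threshold(self, schema):
        m = REModel.initialize(schema, "sdp", 4, seed=0)
        m.W[:] = 0  # uniform predictions, confidence 0.25
        pool = [("a", np.ones(4))]
        assert self_training_iteration(m, pool, tau=0.9) == []

    def test_matches_brute_force_filter_sort(self, schema, rng):
        from sdpre.classifier import predict_proba

        m = REModel.initialize(schema, "sdp", 4, seed=2)
        m.W[:] = rng.standard_normal(m.W.shape) * 3
        pool = [(f"u{i:02d}", rng.standard_normal(4) * 2) for i in range(40)]
        tau, cap = 0.6, 10
        got = self_training_iteration(m, pool, tau=tau, cap=cap)
        expected = []
        for uid, vec in pool:
            p = predict_proba(m, vec)
            if p.max() > tau:
                expected.append((uid, int(p.argmax()), float(p.max())))
        expected.sort(key=lambda t: (-t[2], t[0]))
        assert got == expected[:cap]


class TestBiasReport:
    def test_identical_distributions_tv_zero(self):
        rep = imputation_bias_report(["A", "B", "A"], ["B", "A", "A"])
        assert rep["tv_distance"] == pytest.approx(0.0)

    def test_disjoint_supports_tv_one(self):
        rep = imputation_bias_report(["A", "A"], ["B", "B"])
        assert rep["tv_distance"] == pytest.approx(1.0)

    def test_worked_counts(self):
        imputed = ["A"] * 8 + ["B"] * 2
        gold = ["A"] * 6 + ["B"] * 4
        rep = imputation_bias_report(imputed, gold)
        assert rep["tv_distance"] == pytest.approx(0.2)
        assert rep["imputed_counts"] == {"A": 8, "B": 2}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            imputation_bias_report([], [])
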