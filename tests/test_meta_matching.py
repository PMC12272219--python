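"""Meta-matching: COD ranking, top-M selection, correlation-kernel KRR
stacking, and the finetune variant's head initialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metamatch.meta_matching import (MetaMatchingFinetune, MetaMatchingStacking,
                                     correlation_kernel,
                                     correlation_kernel_matrix, fit_stacking,
                                     rank_outputs_by_cod, select_top_m)
from metamatch.baselines import FinetuneConfig
from metamatch.metrics import cod, pearson


class TestRanking:
    def test_exact_match_ranks_first_with_cod_one(self, rng):
        target = rng.normal(size=20)
        preds = np.column_stack([rng.normal(size=20), target, rng.normal(size=20)])
        cods, ranking = rank_outputs_by_cod(preds, target)
        assert cods[1] == pytest.approx(1.0)
        assert ranking[0] == 1

    def test_ranking_follows_cod_order(self):
        """COD vector [0.5, −0.2, 0.9] must rank as (2, 0, 1)."""
        target = np.array([1.0, -1.0, 2.0, -2.0, 0.5])
        base = np.column_stack([target, target, target])
        # perturb columns to achieve distinct CODs, then check consistency
        rng = np.random.default_rng(0)
        base[:, 0] += 0.7 * rng.normal(size=5)
        base[:, 1] += 1.5 * rng.normal(size=5)
        cods, ranking = rank_outputs_by_cod(base, target)
        assert list(ranking) == list(np.argsort(-cods, kind="stable"))

    def test_ties_break_toward_lower_index(self, rng):
        target = rng.normal(size=10)
        col = rng.normal(size=10)
        preds = np.column_stack([rng.normal(size=10), col, rng.normal(size=10), col])
        _, ranking = rank_outputs_by_cod(preds, target)
        assert list(ranking).index(1) < list(ranking).index(3)

    def test_constant_target_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            rank_outputs_by_cod(rng.normal(size=(5, 2)), np.ones(5))

    def test_matches_brute_force_sort_oracle(self, rng):
        """select_top_m ∘ rank equals evaluate-all/sort/truncate."""
        for _ in range(20):
            K = int(rng.integers(5, 30))
            P = int(rng.integers(2, 12))
            preds = rng.normal(size=(K, P))
            target = rng.normal(size=K)
            cods, ranking = rank_outputs_by_cod(preds, target)
            selected = select_top_m(ranking, K, P)
            oracle = sorted(range(P), key=lambda p: (-cod(target, preds[:, p]), p))
            assert list(selected) == oracle[:min(K, P)]


class TestTopM:
    @pytest.mark.parametrize("K,P,expected", [(20, 33, 20), (50, 33, 33), (1, 33, 1)])
    def test_m_is_min_of_k_and_p(self, K, P, expected):
        assert len(select_top_m(np.arange(P), K, P)) == expected


class TestCorrelationKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=8)
        assert correlation_kernel(x, x) == pytest.approx(1.0)
        assert correlation_kernel(x, -x) == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, 6, elements=st.floats(-10, 10).map(
               lambda v: round(v, 2))),
           st.floats(0.1, 5), st.floats(-3, 3))
    def test_affine_invariance(self, x, a, b):
        y = np.arange(6.0)
        if np.ptp(x) == 0:
            return
        k1 = correlation_kernel(x, y)
        k2 = correlation_kernel(a * x + b, y)
        assert k2 == pytest.approx(k1, abs=1e-8)
        assert correlation_kernel(-a * x + b, y) == pytest.approx(-k1, abs=1e-8)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_kernel(np.ones(4), np.arange(4.0))

    def test_matrix_form_matches_pairwise_and_is_symmetric(self, rng):
        X = rng.normal(size=(6, 5))
        G = correlation_kernel_matrix(X, X)
        np.testing.assert_allclose(G, G.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(G), 1.0)
        for i in range(6):
            for j in range(6):
                assert G[i, j] == pytest.approx(
                    correlation_kernel(X[i], X[j]), abs=1e-12)


class TestStackingKRR:
    def test_dual_solution_matches_dense_solve_oracle(self, rng):
        """α from the fitted model equals (G + λI)⁻¹ y solved independently."""
        K, M, lam = 8, 3, 0.1
        X = rng.normal(size=(K, M))
        y = rng.normal(size=K)
        model = fit_stacking(X, y, lambda_grid=(lam,), cv_folds=4, seed=0)
        yz = (y - y.mean()) / y.std(ddof=1)
        G = correlation_kernel_matrix(X, X)
        alpha_oracle = np.linalg.solve(G + lam * np.eye(K), yz)
        np.testing.assert_allclose(model.model_.dual_coef, alpha_oracle, atol=1e-8)

    def test_lambda_zero_interpolates_shots(self, rng):
        """With a full-rank Gram matrix (which for a correlation kernel needs
        M > K: centered M-vectors span an (M−1)-space), λ=0 interpolates."""
        K, M = 8, 12
        X = rng.normal(size=(K, M))
        y = rng.normal(size=K)
        model = fit_stacking(X, y, lambda_grid=(0.0,), cv_folds=4, seed=0)
        yz = (y - y.mean()) / y.std(ddof=1)
        np.testing.assert_allclose(model.predict(X), yz, atol=1e-6)
        # a test row equal to shot row j predicts y_j
        np.testing.assert_allclose(model.predict(X[[2]]), yz[2], atol=1e-6)

    def test_huge_lambda_shrinks_predictions_to_zero(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit_stacking(X, y, lambda_grid=(1e9,), seed=0)
        assert np.max(np.abs(model.predict(rng.normal(size=(5, 4))))) < 1e-6

    def test_predictions_invariant_to_per_output_affine_rescaling(self, rng):
        """The correlation kernel ignores per-row offset/scale of the feature
        vector, which per-output affine maps preserve... only jointly: scaling
        all selected outputs by one affine map leaves predictions unchanged."""
        K = 12
        preds = rng.normal(size=(K, 5))
        y = preds[:, 0] + 0.3 * rng.normal(size=K)
        test = rng.normal(size=(6, 5))
        m1 = MetaMatchingStacking(lambda_grid=(0.1,), seed=0).fit(preds, y)
        p1 = m1.predict(test)
        m2 = MetaMatchingStacking(lambda_grid=(0.1,), seed=0).fit(
            2.5 * preds - 1.0, y)
        p2 = m2.predict(2.5 * test - 1.0)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_selection_uses_top_m_rule(self, rng):
        K, P = 6, 9  # M = min(6, 9) = 6
        preds = rng.normal(size=(K, P))
        y = rng.normal(size=K)
        model = MetaMatchingStacking(lambda_grid=(0.1,), cv_folds=3, seed=0).fit(preds, y)
        assert len(model.model_.selected_output_indices) == 6

    def test_exact_output_dominates_predictions_at_small_lambda(self, rng):
        """When one base output equals the target, small-λ stacking tracks the
        target on fresh test rows; the correlation kernel still mixes in the
        unrelated outputs, so agreement is strong but not exact."""
        K, P, n_test = 30, 10, 20
        z = rng.normal(size=K + n_test)
        preds = np.column_stack([rng.normal(size=K + n_test) for _ in range(P - 1)]
                                + [z])
        y = z.copy()
        model = MetaMatchingStacking(lambda_grid=(1e-6,), cv_folds=5, seed=0).fit(
            preds[:K], y[:K])
        out = model.predict(preds[K:])
        yz = (y[K:] - y[:K].mean()) / y[:K].std(ddof=1)
        assert pearson(out, yz) > 0.7

    def test_single_output_model_falls_back_to_ridge(self, rng):
        K = 10
        preds = rng.normal(size=(K, 1))
        y = 2 * preds[:, 0] + 0.1 * rng.normal(size=K)
        model = MetaMatchingStacking(seed=0).fit(preds, y)
        assert model._single_feature
        out = model.predict(preds)
        assert pearson(out, y) > 0.9

    def test_m_mismatch_at_predict_errors(self, rng):
        model = fit_stacking(rng.normal(size=(10, 3)), rng.normal(size=10),
                             lambda_grid=(0.1,), seed=0)
        with pytest.raises(ValueError, match="selected"):
            model.predict(rng.normal(size=(2, 4)))


class TestMetaMatchingFinetune:
    def test_head_seeded_from_best_cod_node(self, tiny_base, tiny_pool):
        """With the selected node's weights as initialization, the un-finetuned
        head reproduces that node's predictions (initialization contract)."""
        y = tiny_pool.table.values[:40, 0]
        model = MetaMatchingFinetune(
            tiny_base, FinetuneConfig(lr_grid=(1e-4,), max_epochs=1, seed=0))
        feats = tiny_pool.trunk[:40]
        icv = tiny_pool.icv[:40]
        model.fit(feats, y, icv)
        # provenance equals the argmax-COD node of the base predictions
        from metamatch.tables import apply_norm_stats, fit_norm_stats

        start = tiny_base.config_.n_blocks - 1
        icv_z = tiny_base._icv_z(icv)
        base_preds = tiny_base.net_.predict(feats, icv_z, start_block=start)
        yz = apply_norm_stats(y[:, None], fit_norm_stats(y[:, None])).ravel()
        _, ranking = rank_outputs_by_cod(base_preds, yz)
        assert model.source_output_ == int(ranking[0])

    def test_initial_head_equals_selected_node_before_training(self, tiny_base,
                                                               tiny_pool):
        """Zero effective finetuning: head weights start as the chosen node's."""
        y = tiny_pool.table.values[:40, 0]
        model = MetaMatchingFinetune(
            tiny_base, FinetuneConfig(lr_grid=(0.0,), max_epochs=1, seed=0))
        model.fit(tiny_pool.trunk[:40], y, tiny_pool.icv[:40])
        p = model.source_output_
        np.testing.assert_allclose(
            model.net_.head.params["W"].ravel(),
            tiny_base.net_.head.params["W"][:, p], atol=1e-12)

    def test_provenance_recovers_copied_phenotype(self, rng):
        """A meta-test phenotype that is a noisy copy of meta-training
        phenotype #2 selects node 2 in the vast majority of seeded draws."""
        hits = 0
        for rep in range(20):
            r2 = np.random.default_rng(100 + rep)
            K = 40
            outputs = r2.normal(size=(K, 4))
            y = outputs[:, 2] + 0.3 * r2.normal(size=K)
            _, ranking = rank_outputs_by_cod(outputs, (y - y.mean()) / y.std(ddof=1))
            hits += ranking[0] == 2
        assert hits >= 19


class TestStackingBeatsWeakBaselines:
    def test_stacking_tracks_correlated_phenotype(self, tiny_bench, tiny_base,
                                                  tiny_pool):
        """On the 0.8-overlap phenotype, stacking attains positive test r."""
        y = tiny_pool.table.values[:, 0]
        K = 50
        model = MetaMatchingStacking(seed=0).fit(tiny_pool.base_preds[:K], y[:K])
        preds = model.predict(tiny_pool.base_preds[K:])
        assert pearson(y[K:], preds) > 0.3
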