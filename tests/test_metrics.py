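"""Accuracy metrics and comparison statistics against independent oracles."""

import numpy as np
import pytest
import scipy.stats

from metamatch.metrics import (EvalRecord, aggregate, bootstrap_compare, cod,
                               cohens_d, fdr_bh, mae, pearson,
                               phenotype_overlap_analysis)
from metamatch.tables import PhenotypeTable


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        y = [1.0, 2.0, 5.0]
        assert pearson(y, y) == pytest.approx(1.0)
        assert pearson(y, [-v for v in y]) == pytest.approx(-1.0)

    def test_hand_case_matches_direct_formula(self):
        # cov([1,2,3],[1,2,4]) / (sigma sigma), evaluated by hand
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(3 / np.sqrt(2 * 14 / 3))

    def test_agrees_with_scipy(self, rng):
        y, yhat = rng.normal(size=(2, 40))
        assert pearson(y, yhat) == pytest.approx(scipy.stats.pearsonr(y, yhat)[0])

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])


class TestCod:
    def test_identity_prediction_gives_one(self):
        assert cod([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_gives_zero(self):
        assert cod([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_case(self):
        # SS_res = 1+4+9 = 14, SS_tot = 2 -> 1 - 7 = -6
        assert cod([1, 2, 3], [0, 0, 0]) == pytest.approx(-6.0)

    def test_constant_target_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cod([2, 2, 2], [1, 2, 3])

    def test_equals_r_squared_for_least_squares_fit(self, rng):
        """COD == r² exactly when ŷ is the LS affine fit of y on a predictor."""
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        assert cod(y, yhat) == pytest.approx(pearson(y, x) ** 2)

    def test_not_invariant_to_eval_zspace_but_pearson_is(self, rng):
        """Pearson is scale-free; COD depends on the z-scoring of y."""
        y = rng.normal(size=25)
        yhat = y + rng.normal(size=25)
        y2, yhat2 = 3 * y + 1, yhat  # rescale target only
        assert pearson(y, yhat) == pytest.approx(pearson(y2, yhat2))
        assert cod(y, yhat) != pytest.approx(cod(y2, yhat2))


class TestMae:
    @pytest.mark.parametrize("y,yhat,expected",
                             [([1, 2], [1, 2], 0.0),
                              ([1, 2], [2, 3], 1.0),
                              ([0, 2], [1, 1], 1.0)])
    def test_cases(self, y, yhat, expected):
        assert mae(y, yhat) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestCohensD:
    def test_zero_for_identical_distributions(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_antisymmetric(self, rng):
        a, b = rng.normal(size=(2, 20))
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_hand_case_with_pooled_std(self):
        # means 1 and 2; each var 2 (ddof=1); pooled std sqrt(2)
        assert cohens_d([0, 2], [1, 3]) == pytest.approx(-1 / np.sqrt(2))

    def test_zero_pooled_std_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1, 1], [2, 2])


class TestFdrBH:
    def test_hand_step_up(self):
        flags = fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_and_all_zeros(self):
        assert fdr_bh([1.0] * 5).sum() == 0
        assert fdr_bh([0.0] * 5).sum() == 5

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            expected = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(fdr_bh(p, 0.05), expected)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def _records(method, values, K=10):
    """values: repeats × phenotypes matrix of pearson_r."""
    out = []
    for r in range(values.shape[0]):
        for j in range(values.shape[1]):
            out.append(EvalRecord(method, K, r, f"ph{j}",
                                  float(values[r, j]), 0.0, 1.0, 50))
    return out


class TestAggregate:
    def test_mean_across_phenotypes_then_repeats(self):
        vals = np.array([[0.2, 0.4], [0.6, 0.8]])
        agg = aggregate(_records("m", vals))
        assert sorted(agg["value"]) == pytest.approx([0.3, 0.7])

    def test_single_phenotype_equals_record(self):
        agg = aggregate(_records("m", np.array([[0.5]])))
        assert agg["value"].tolist() == [0.5]

    def test_incomplete_grid_errors(self):
        recs = _records("m", np.array([[0.1, 0.2], [0.3, 0.4]]))
        with pytest.raises(ValueError, match="incomplete"):
            aggregate(recs[:-1])


class TestBootstrapCompare:
    def test_identical_methods_give_p_one(self, rng):
        vals = rng.normal(0.5, 0.1, size=(10, 4))
        recs = _records("a", vals) + _records("b", vals)
        res = bootstrap_compare(recs, "a", "b", K=10, n_boot=200, seed=0)
        assert res.p_value == 1.0
        assert res.mean_difference == 0.0

    def test_constant_shift_hits_p_floor(self, rng):
        vals = rng.normal(0.0, 0.01, size=(8, 3))
        recs = _records("a", vals + 0.9) + _records("b", vals)
        res = bootstrap_compare(recs, "a", "b", K=10, n_boot=250, seed=0)
        assert res.p_value == pytest.approx(1 / 250)
        assert res.mean_difference == pytest.approx(0.9)

    def test_renaming_phenotypes_invariant(self, rng):
        """Only the paired values matter, not the phenotype labels."""
        vals_a = rng.normal(0.4, 0.1, size=(6, 3))
        vals_b = rng.normal(0.3, 0.1, size=(6, 3))
        res1 = bootstrap_compare(_records("a", vals_a) + _records("b", vals_b),
                                 "a", "b", K=10, n_boot=300, seed=4)

        def rename(recs):
            for r in recs:
                r.phenotype = r.phenotype.replace("ph", "trait_")
            return recs

        res2 = bootstrap_compare(rename(_records("a", vals_a)) +
                                 rename(_records("b", vals_b)),
                                 "a", "b", K=10, n_boot=300, seed=4)
        assert res1.p_value == res2.p_value
        assert res1.mean_difference == res2.mean_difference

    def test_unpaired_cells_error(self, rng):
        recs = _records("a", rng.normal(0, 0.1, size=(4, 2)))
        recs += _records("b", rng.normal(0, 0.1, size=(4, 3)))
        with pytest.raises(ValueError, match="paired"):
            bootstrap_compare(recs, "a", "b", K=10, n_boot=10, seed=0)


class TestOverlapAnalysis:
    def _tables(self, rng, corr_structure=True):
        n = 400
        z = rng.normal(size=n)
        train_vals = np.column_stack([z + 0.3 * rng.normal(size=n),
                                      rng.normal(size=n)])
        if corr_structure:
            test_vals = np.column_stack([z + 0.3 * rng.normal(size=n)])
        else:
            test_vals = rng.normal(size=(n, 1))
        ids = [f"s{i}" for i in range(n)]
        return (PhenotypeTable(ids, ["tr0", "tr1"], train_vals),
                PhenotypeTable(ids, ["te0"], test_vals))

    def test_duplicated_phenotype_gives_corr_one(self, rng):
        ids = [f"s{i}" for i in range(50)]
        y = rng.normal(size=(50, 1))
        tr = PhenotypeTable(ids, ["a"], y)
        te = PhenotypeTable(ids, ["b"], y.copy())
        df = phenotype_overlap_analysis(tr, te, {"b": 0.1})
        assert df["max_abs_corr"].iloc[0] == pytest.approx(1.0)

    def test_independent_phenotypes_have_small_max_corr(self, rng):
        tr, te = self._tables(rng, corr_structure=False)
        df = phenotype_overlap_analysis(tr, te, {})
        assert df["max_abs_corr"].iloc[0] < 0.15

    def test_row_per_test_phenotype_and_error_without_overlap(self, rng):
        tr, te = self._tables(rng)
        assert len(phenotype_overlap_analysis(tr, te, {})) == te.n_phenotypes
        te2 = PhenotypeTable([f"x{i}" for i in range(te.n_participants)],
                             te.phenotype_names, te.values)
        with pytest.raises(ValueError, match="shared"):
            phenotype_overlap_analysis(tr, te2, {})
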