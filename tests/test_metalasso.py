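import numpy as np
import pandas as pd
import pytest

from mirreg import metalasso as ml
from mirreg.metalasso import SELECTION_TOL


class TestFwlResidualize:
    def test_intercept_only_centers(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        x2 = rng.normal(size=(20, 3))
        yt, x2t = ml.fwl_residualize(y, np.empty((20, 0)), x2)
        assert np.allclose(yt, y - y.mean(), atol=1e-12)

    def test_perfect_projection_zeroes_response(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=15)
        yt, _ = ml.fwl_residualize(y, y[:, None], rng.normal(size=(15, 2)))
        assert np.allclose(yt, 0.0, atol=1e-10)

    def test_matches_joint_ols(self):
        # FWL theorem: OLS of residualized y on residualized X2 equals the
        # X2 block of the joint OLS of y on [X1, 1, X2]
        rng = np.random.default_rng(2)
        n = 50
        x1 = rng.normal(size=(n, 2))
        x2 = rng.normal(size=(n, 5))
        y = x1 @ [1.0, -2.0] + x2 @ rng.normal(size=5) + rng.normal(size=n)
        yt, x2t = ml.fwl_residualize(y, x1, x2)
        b_fwl, *_ = np.linalg.lstsq(x2t, yt, rcond=None)
        joint = np.column_stack([x1, np.ones(n), x2])
        b_joint, *_ = np.linalg.lstsq(joint, y, rcond=None)
        assert np.allclose(b_fwl, b_joint[3:], atol=1e-8)

    def test_rank_deficient_background_handled(self):
        rng = np.random.default_rng(3)
        x1 = np.ones((30, 2))  # collinear with the intercept
        y = rng.normal(size=30)
        yt, _ = ml.fwl_residualize(y, x1, rng.normal(size=(30, 2)))
        assert np.allclose(yt, y - y.mean(), atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ml.fwl_residualize(np.ones(3), np.ones((3, 3)), np.ones((3, 1)))


class TestHierarchicalSubsets:
    def test_500_samples_gives_25_of_320(self):
        subs = ml.hierarchical_subsets(500, seed=0)
        assert len(subs) == 25
        assert all(len(s) == 320 for s in subs)

    def test_smallest_exact_case(self):
        subs = ml.hierarchical_subsets(25, seed=0)
        assert len(subs) == 25 and all(len(s) == 16 for s in subs)

    def test_deterministic_given_seed(self):
        a = ml.hierarchical_subsets(100, seed=42)
        b = ml.hierarchical_subsets(100, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ml.hierarchical_subsets(24)

    def test_subsets_are_valid_indices(self):
        for s in ml.hierarchical_subsets(60, seed=7):
            assert len(np.unique(s)) == len(s)
            assert s.min() >= 0 and s.max() < 60


class TestFitMetaLasso:
    def _noise_datasets(self, seed, m=3, n=30, p=4):
        rng = np.random.default_rng(seed)
        return [(rng.normal(size=n), rng.normal(size=(n, p)))
                for _ in range(m)]

    def test_zero_response_gives_origin(self):
        rng = np.random.default_rng(0)
        ds = [(np.zeros(20), rng.normal(size=(20, 3))) for _ in range(2)]
        fit = ml.fit_meta_lasso(ds, 1.0, 1.0)
        assert np.all(fit.g == 0) and np.all(fit.zeta == 0)

    def test_huge_w_silences_everything(self):
        fit = ml.fit_meta_lasso(self._noise_datasets(1), 1e6, 1.0)
        assert not fit.selected.any()

    def test_single_dataset_fixed_zeta_matches_lasso(self):
        # oracle: scikit-learn Lasso, objective (1/2n)||y-Xb||^2 + a||b||_1
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(4)
        n, p = 80, 10
        x = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:3] = [1.2, -0.8, 0.6]
        y = x @ beta + rng.normal(0, 0.5, n)
        w = 20.0
        fit = ml.fit_meta_lasso([(y, x)], w, 0.0, fix_zeta=1.0)
        xs = (x - x.mean(0)) / x.std(0)
        oracle = Lasso(alpha=w / n, tol=1e-12, max_iter=200000).fit(xs, y)
        assert np.allclose(fit.beta[0] * x.std(0), oracle.coef_, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_monotone_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        m, n, p = 4, 25, 6
        ds = []
        beta = rng.normal(size=p) * (rng.random(p) < 0.5)
        for _ in range(m):
            x = rng.normal(size=(n, p))
            ds.append((x @ beta + rng.normal(0, 1.0, n), x))
        fit = ml.fit_meta_lasso(ds, 3.0, 1.0)
        diffs = np.diff(fit.objective_path)
        assert (diffs >= -1e-10).all()

    def test_large_lambda_zeroes_zeta(self):
        ds = self._noise_datasets(5)
        fit = ml.fit_meta_lasso(ds, 0.5, 1e8)
        assert np.all(fit.zeta == 0)
        # model reduces to intercepts only
        assert np.all(fit.beta == 0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(6)
        n, p = 60, 5
        x = rng.normal(size=(n, p))
        y = x[:, 1] * 1.5 + rng.normal(0, 0.3, n)
        perm = [3, 1, 4, 0, 2]
        f1 = ml.fit_meta_lasso([(y, x)], 5.0, 2.0)
        f2 = ml.fit_meta_lasso([(y, x[:, perm])], 5.0, 2.0)
        assert np.allclose(f1.g[perm], f2.g, atol=1e-6)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ml.fit_meta_lasso([(np.array([1.0, np.nan]), np.ones((2, 1)))],
                              1.0, 1.0)


class TestSelectTuning:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(0)
        ds = [(rng.normal(size=30), rng.normal(size=(30, 3)))]
        w, lam, _ = ml.select_tuning(ds, (0.2,), (0.1,))
        w_max, lam_max = ml.penalty_scales(ds)
        assert w == pytest.approx(0.2 * w_max)
        assert lam == pytest.approx(0.1 * lam_max)

    def test_pure_noise_selects_nothing_usually(self):
        zero = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            n, p = 50, 10
            x = rng.normal(size=(n, p))
            y = rng.normal(0, 1.0, n)
            subs = ml.hierarchical_subsets(n, seed=rng)
            ds = [(y[i], x[i]) for i in subs]
            _, _, fit = ml.select_tuning(ds, (0.5, 0.2, 0.1, 0.05),
                                         (0.3, 0.1))
            if not fit.selected.any():
                zero += 1
        assert zero / reps >= 0.9

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(9)
        n, p = 100, 8
        x = rng.normal(size=(n, p))
        y = 1.5 * x[:, 2] - 1.0 * x[:, 5] + rng.normal(0, 0.5, n)
        subs = ml.hierarchical_subsets(n, seed=rng)
        ds = [(y[i], x[i]) for i in subs]
        _, _, fit = ml.select_tuning(ds, (0.5, 0.2, 0.1, 0.05), (0.3, 0.1))
        assert {2, 5} <= set(np.flatnonzero(fit.selected))


class TestSelectRegulators:
    def _fit(self, g):
        g = np.asarray(g, dtype=float)
        m, p = 3, len(g)
        zeta = np.ones((m, p))
        return ml.MetaLassoFit(g=g, zeta=zeta, beta=g[None, :] * zeta,
                               intercepts=np.zeros(m), w=1.0, lam=1.0,
                               n_iter=1, converged=True,
                               objective_path=np.array([0.0]))

    def test_nonzero_entries_selected(self):
        sel = ml.select_regulators(self._fit([0.0, 0.4, 0.0]),
                                   ["a", "b", "c"], ["TF", "miRNA", "miRNA"],
                                   "g1", ("C", "I"))
        assert list(sel.regulator_id) == ["b"]
        assert sel.iloc[0]["sign"] == 1

    def test_zero_fit_empty_selection(self):
        sel = ml.select_regulators(self._fit([0.0, 0.0]), ["a", "b"],
                                   ["TF", "TF"], "g1", ("C", "I"))
        assert len(sel) == 0


class TestHierarchicalConsistency:
    def _sel(self, rows):
        return pd.DataFrame(rows, columns=["cancer_type", "stage", "gene_id",
                                           "regulator_id", "kind"])

    def test_unanimous_regulator_in_cancer_set(self):
        rows = [("C1", s, "g1", "m1", "miRNA") for s in "I II III IV".split()]
        cancer, _ = ml.hierarchical_consistency(self._sel(rows))
        assert len(cancer) == 1 and cancer.iloc[0].n_stages == 4

    def test_single_stage_excluded_at_half(self):
        rows = [("C1", "I", "g1", "m1", "miRNA"),
                ("C1", "II", "g1", "m2", "miRNA"),
                ("C1", "III", "g1", "m2", "miRNA"),
                ("C1", "IV", "g1", "m2", "miRNA")]
        cancer, _ = ml.hierarchical_consistency(self._sel(rows), 0.5)
        assert set(cancer.regulator_id) == {"m2"}

    def test_pan_cancer_regulator_found(self):
        rows = []
        for c in ["C1", "C2", "C3"]:
            for s in ["I", "II"]:
                rows.append((c, s, "g1", "mPan", "miRNA"))
        _, common = ml.hierarchical_consistency(self._sel(rows))
        assert list(common.regulator_id) == ["mPan"]
        assert common.iloc[0].n_cancers == 3
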