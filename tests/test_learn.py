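"""The l1l2 solver, RLS, and the nested cross-validation tasks.

The independent oracle for the l1l2 objective is scikit-learn's
coordinate-descent ElasticNet: with alpha = l1/2 + mu and
l1_ratio = (l1/2)/alpha, its objective is exactly half of ours, so the
two minimizers coincide.
"""

import numpy as np
import pytest

from gosig import (
    LabelVector,
    SolverConfig,
    classify,
    l1_max_bound,
    l1l2_objective,
    l1l2_solve,
    rls_solve,
    run_l1l2_task,
    run_rls_task,
)
from gosig.errors import ContractError, StratificationError
from gosig.learn import RLS_KEY, l1l2_kkt_residual, stratified_folds, task_seed
from gosig.subsets import L1L2FS, RLS, TermSubset


def oracle_solve(X, y, l1, mu):
    """ElasticNet reformulation of the l1l2 objective (independent route)."""
    from sklearn.linear_model import ElasticNet

    alpha = l1 / 2.0 + mu
    model = ElasticNet(
        alpha=alpha, l1_ratio=(l1 / 2.0) / alpha, fit_intercept=False,
        tol=1e-12, max_iter=200000,
    )
    return model.fit(X, y).coef_


def random_problem(rng, n=None, p=None):
    n = n or int(rng.integers(10, 41))
    p = p or int(rng.integers(5, 61))
    X = rng.normal(size=(n, p))
    y = np.sign(rng.normal(size=n))
    y[y == 0] = 1.0
    return X, y


class TestL1l2Solve:
    def test_full_shrinkage_bound_gives_zero(self, rng):
        X, y = random_problem(rng)
        l1 = l1_max_bound(X, y)
        w = l1l2_solve(X, y, l1 * 1.0001, mu=0.0)
        assert np.all(w == 0.0)

    def test_penalty_free_limit_is_least_squares(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        w = l1l2_solve(X, y, l1=0.0, mu=0.0, tol=1e-10, max_iter=100000)
        w_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(w, w_ols, atol=1e-6)

    def test_matches_convex_oracle_on_random_instance(self, rng):
        X, y = random_problem(rng, n=20, p=5)
        w = l1l2_solve(X, y, 0.1, 0.05, tol=1e-9, max_iter=100000)
        w_star = oracle_solve(X, y, 0.1, 0.05)
        ours = l1l2_objective(X, y, w, 0.1, 0.05)
        theirs = l1l2_objective(X, y, w_star, 0.1, 0.05)
        assert abs(ours - theirs) < 1e-6
        assert l1l2_kkt_residual(X, y, w, 0.1, 0.05) <= 1e-9 * 10

    def test_kkt_residual_zero_only_at_optimum(self, rng):
        X, y = random_problem(rng, n=15, p=8)
        w = l1l2_solve(X, y, 0.2, 0.1, tol=1e-8, max_iter=50000)
        assert l1l2_kkt_residual(X, y, w, 0.2, 0.1) <= 1e-7
        assert l1l2_kkt_residual(X, y, w + 0.5, 0.2, 0.1) > 1e-3

    def test_support_monotone_in_l1_weight(self, rng):
        X, y = random_problem(rng, n=30, p=40)
        l1_hi = l1_max_bound(X, y)
        grid = np.geomspace(1e-3 * l1_hi, l1_hi, 12)
        sizes = [
            int(np.count_nonzero(l1l2_solve(X, y, l1, 0.01, tol=1e-7, max_iter=50000)))
            for l1 in grid
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_mu_admits_more_correlated_variables(self):
        """Two strongly correlated informative columns: at larger mu both
        enter the support more often than at mu ~ 0 (the correlation
        parameter's advertised role), checked across seeds."""
        both_small = both_large = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([1.0, -1.0], n // 2)
            X = rng.normal(size=(n, 12))
            X[:, 0] = y + 0.5 * rng.normal(size=n)  # correlated copies of
            X[:, 1] = y + 0.5 * rng.normal(size=n)  # the class signal
            l1 = 0.6 * l1_max_bound(X, y)
            for mu, counter in ((1e-4, "s"), (1.0, "l")):
                w = l1l2_solve(X, y, l1, mu, tol=1e-8, max_iter=50000)
                both = (w[0] != 0) and (w[1] != 0)
                if counter == "s":
                    both_small += both
                else:
                    both_large += both
        assert both_large > both_small


class TestRls:
    def test_square_invertible_interpolates(self, rng):
        X = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        y = np.array([1.0, -1.0, 1.0, -1.0])
        w = rls_solve(X, y, lam=0.0)
        np.testing.assert_allclose(X @ w, y, atol=1e-8)

    def test_ridge_limit_shrinks_norm_monotonically(self, rng):
        X, y = random_problem(rng, n=10, p=6)
        norms = [np.linalg.norm(rls_solve(X, y, lam)) for lam in (0.0, 1.0, 10.0, 1e4)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3

    def test_closed_form_for_positive_lam(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        y = np.array([1.0, -1.0, 1.0])
        lam = 0.5
        n = 3
        expected = np.linalg.solve(X.T @ X + n * lam * np.eye(2), X.T @ y)
        np.testing.assert_allclose(rls_solve(X, y, lam), expected, atol=1e-12)


class TestClassify:
    def test_zero_weights_tie_to_plus_one(self, rng):
        X = rng.normal(size=(7, 3))
        assert np.all(classify(np.zeros(3), X) == 1.0)

    def test_separable_one_dimensional(self):
        X = np.array([[2.0], [-3.0], [4.0], [-1.0]])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert np.all(classify(np.array([1.0]), X) == y)

    def test_error_equals_sign_mismatch_recount(self, rng):
        X = rng.normal(size=(50, 4))
        w = rng.normal(size=4)
        y = np.sign(rng.normal(size=50))
        y[y == 0] = 1.0
        pred = classify(w, X)
        recount = sum(1 for a, b in zip(np.sign(X @ w + 0.0), y) if (a >= 0) != (b > 0))
        assert float((pred != y).mean()) == recount / 50


def _make_subset(values, technique, term="GO:9000123"):
    p, n = values.shape
    return TermSubset(
        term_id=term,
        probeset_ids=[f"p{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        values=values,
        technique=technique,
    )


def _labels(y):
    return LabelVector({f"s{j}": int(v) for j, v in enumerate(y)})


FAST = dict(mu_values=(0.1,), n_l1=8, inner_k=3, outer_k=4, tol=1e-4, max_iter=2000)


class TestRunL1l2Task:
    def test_split_count_and_confusion_consistency(self, rng):
        values = rng.normal(size=(50, 24))
        y = np.repeat([1, -1], 12)
        res = run_l1l2_task(_make_subset(values, L1L2FS), _labels(y),
                            SolverConfig(seed=3, **FAST))
        for pm in res.per_mu.values():
            assert len(pm.splits) == 4
            for s in pm.splits:
                tp, tn, fp, fn = s.confusion
                assert tp + tn + fp + fn == 6  # outer test-fold size
                assert s.test_error == (fp + fn) / 6
            assert all(0 <= f <= 4 for f in pm.frequencies.values())

    def test_informative_variable_dominates(self):
        """One perfectly separating variable among noise: frequency K, low error."""
        rng = np.random.default_rng(7)
        n = 40
        y = np.repeat([1, -1], n // 2)
        values = rng.normal(size=(21, n))
        values[0] = 2.0 * y + 0.25 * rng.normal(size=n)  # gap ~ 4 SD units
        res = run_l1l2_task(_make_subset(values, L1L2FS), _labels(y),
                            SolverConfig(seed=1, **FAST))
        pm = res.per_mu["mu0"]
        assert pm.frequencies["p0"] == 4
        assert pm.mean_test_error <= 0.1

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=(50, 24))
        y = np.repeat([1, -1], 12)
        cfg = SolverConfig(seed=9, **FAST)
        a = run_l1l2_task(_make_subset(values, L1L2FS), _labels(y), cfg)
        b = run_l1l2_task(_make_subset(values, L1L2FS), _labels(y), cfg)
        assert a.to_dict() == b.to_dict()

    def test_stratification_error_on_tiny_class(self, rng):
        values = rng.normal(size=(50, 10))
        y = np.array([1] * 8 + [-1] * 2)
        with pytest.raises(StratificationError):
            run_l1l2_task(_make_subset(values, L1L2FS), _labels(y),
                          SolverConfig(seed=0, **FAST))

    def test_rejects_misrouted_subset(self, rng):
        values = rng.normal(size=(5, 24))
        y = np.repeat([1, -1], 12)
        with pytest.raises(ContractError):
            run_l1l2_task(_make_subset(values, RLS), _labels(y), SolverConfig(**FAST))


class TestRunRlsTask:
    def test_separable_subset_zero_error_full_frequency(self):
        rng = np.random.default_rng(5)
        n = 24
        y = np.repeat([1, -1], n // 2)
        values = np.vstack([3.0 * y + 0.1 * rng.normal(size=n),
                            -3.0 * y + 0.1 * rng.normal(size=n)])
        res = run_rls_task(_make_subset(values, RLS), _labels(y),
                           SolverConfig(seed=2, outer_k=4))
        pm = res.per_mu[RLS_KEY]
        assert pm.mean_test_error == 0.0
        assert all(f == 4 for f in pm.frequencies.values())

    def test_single_pseudo_mu_entry_keyed_rls(self, rng):
        values = rng.normal(size=(3, 20))
        y = np.repeat([1, -1], 10)
        res = run_rls_task(_make_subset(values, RLS), _labels(y), SolverConfig(seed=0))
        assert list(res.per_mu) == [RLS_KEY]
        assert res.per_mu[RLS_KEY].mu is None
        assert res.technique == RLS


class TestFoldsAndSeeds:
    def test_stratified_folds_contain_both_classes(self, rng):
        y = np.array([1.0] * 13 + [-1.0] * 7)
        folds = stratified_folds(y, 4, rng)
        assert sorted(np.concatenate(folds).tolist()) == list(range(20))
        for f in folds:
            assert {1.0, -1.0} <= set(y[f])

    def test_task_seed_depends_only_on_term_and_run_seed(self):
        a = task_seed(5, "GO:1").generate_state(4)
        b = task_seed(5, "GO:1").generate_state(4)
        c = task_seed(5, "GO:2").generate_state(4)
        assert np.array_equal(a, b) and not np.array_equal(a, c)
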