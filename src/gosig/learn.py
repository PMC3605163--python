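"""The knowledge-discovery engine.

Variable selection on each GO-term subset is an embedded l1l2-regularized
least-squares problem,

    J(w) = (1/n) ||y - X w||_2^2  +  mu ||w||_2^2  +  l1 ||w||_1 ,

solved by accelerated iterative soft-thresholding (FISTA).  The l1 weight
controls sparsity; the correlation parameter ``mu`` governs how many
correlated variables enter the selected list together (mu -> 0 gives
lasso-like behavior that picks one representative per correlated group,
larger mu spreads weight over the group).  Model selection is a full
nested K-fold cross-validation: inner folds pick the l1 weight, outer
folds estimate the error and record, per split, which variables were
selected; selection frequencies across outer splits are the stability
signal consumed downstream.

Prediction uses the standard two-stage scheme: the l1l2 support is
refitted with plain regularized least squares (regularization 0 by
default) and classified by the sign rule.  Small subsets skip model
selection entirely and are classified with RLS on all variables.

Loss scaling is fixed at (1/n)||y - Xw||^2 so penalty grids are
independent of sample count; the full-shrinkage bound is
l1_max = 2 max_j |(1/n) sum_i X_ij y_i|.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np

from .errors import ContractError, StratificationError
from .io import LabelVector
from .subsets import L1L2FS, RLS, TermSubset

logger = logging.getLogger(__name__)

#: key of the single pseudo-mu entry in RLS results
RLS_KEY = "RLS"


# ---------------------------------------------------------------------------
# solvers


def l1_max_bound(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest l1 weight at which the l1l2 solution is exactly zero."""
    n = X.shape[0]
    return 2.0 * np.max(np.abs(X.T @ y)) / n


def l1l2_kkt_residual(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, l1: float, mu: float
) -> float:
    """Max-norm violation of the subgradient optimality conditions at ``w``.

    Zero at the exact minimizer of J; the solver stops when this drops
    below its tolerance.
    """
    n = X.shape[0]
    grad = (2.0 / n) * (X.T @ (X @ w - y)) + 2.0 * mu * w
    nz = w != 0
    res_nz = np.abs(grad[nz] + l1 * np.sign(w[nz])) if nz.any() else np.array([0.0])
    res_z = np.maximum(np.abs(grad[~nz]) - l1, 0.0) if (~nz).any() else np.array([0.0])
    return max(res_nz.max(initial=0.0), res_z.max(initial=0.0))


def l1l2_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, l1: float, mu: float
) -> float:
    n = X.shape[0]
    resid = y - X @ w
    return float(resid @ resid / n + mu * (w @ w) + l1 * np.abs(w).sum())


def _soft_threshold(v: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


def l1l2_solve(
    X: np.ndarray,
    y: np.ndarray,
    l1: float,
    mu: float,
    tol: float = 1e-6,
    max_iter: int = 10000,
    w0: np.ndarray | None = None,
    return_info: bool = False,
):
    """Minimize J(w) by FISTA (accelerated proximal gradient).

    Parameters
    ----------
    X : (n, p) design matrix, y : (n,) labels in {-1, +1}
    l1, mu : non-negative penalty weights
    tol : stop when the subgradient (KKT) residual falls below this
    w0 : optional warm start

    Returns the weight vector, or ``(w, n_iter, converged)`` with
    ``return_info``.  Non-convergence within ``max_iter`` is logged, not
    fatal.
    """
    if l1 < 0 or mu < 0:
        raise ValueError("penalty weights must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    w = np.zeros(p) if w0 is None else np.array(w0, dtype=float)

    # Lipschitz constant of the smooth part's gradient
    smax = np.linalg.norm(X, 2)
    L = 2.0 * (smax * smax / n + mu)
    if L == 0.0:  # X identically zero
        return (w, 0, True) if return_info else w
    step = 1.0 / L
    thr = l1 * step

    z = w.copy()
    t = 1.0
    converged = False
    it = 0
    XtX = None
    Xty = X.T @ y
    if p <= n or p <= 400:  # precompute Gram when cheap
        XtX = X.T @ X
    for it in range(1, max_iter + 1):
        if XtX is not None:
            grad = (2.0 / n) * (XtX @ z - Xty) + 2.0 * mu * z
        else:
            grad = (2.0 / n) * (X.T @ (X @ z - y)) + 2.0 * mu * z
        w_new = _soft_threshold(z - step * grad, thr)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = w_new + ((t - 1.0) / t_new) * (w_new - w)
        w, t = w_new, t_new
        if it % 10 == 0 or it == max_iter:
            if l1l2_kkt_residual(X, y, w, l1, mu) <= tol:
                converged = True
                break
    if not converged and l1l2_kkt_residual(X, y, w, l1, mu) <= tol:
        converged = True
    if not converged:
        logger.warning(
            "l1l2_solve did not reach tol=%.2g in %d iterations (l1=%.3g, mu=%.3g)",
            tol, max_iter, l1, mu,
        )
    return (w, it, converged) if return_info else w


def rls_solve(X: np.ndarray, y: np.ndarray, lam: float = 0.0) -> np.ndarray:
    """Regularized least squares, (1/n)||y - Xw||^2 + lam ||w||^2.

    ``lam = 0`` returns the minimum-norm least-squares solution
    (pseudo-inverse); ``lam > 0`` solves (X'X + n lam I) w = X'y.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    n, p = X.shape
    return np.linalg.solve(X.T @ X + n * lam * np.eye(p), X.T @ y)


def classify(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Sign-rule labels in {-1, +1}; an exact zero score maps to +1."""
    return np.where(X @ w >= 0.0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass
class SolverConfig:
    """Everything the nested-CV learner needs, including its RNG seed.

    ``mu_values=None`` uses {1e-2, 1e-1, 1} scaled by trace(X'X)/(n p)
    of the standardized subset (~= the mean column energy);
    ``l1_grid=None`` uses, per outer training fold, a geometric
    grid of ``n_l1`` values from 1e-3 * l1_max up to the full-shrinkage
    bound l1_max of that fold.
    """

    mu_values: tuple[float, ...] | None = None
    l1_grid: tuple[float, ...] | None = None
    n_l1: int = 20
    inner_k: int = 3
    outer_k: int = 4
    tol: float = 1e-5
    max_iter: int = 5000
    seed: int = 0
    standardize: bool = True
    rls_lam: float = 0.0

    def __post_init__(self) -> None:
        if self.inner_k < 2 or self.outer_k < 2:
            raise ValueError("inner_k and outer_k must be >= 2")
        if self.mu_values is not None and any(m < 0 for m in self.mu_values):
            raise ValueError("mu values must be non-negative")
        if self.l1_grid is not None and (
            not self.l1_grid or any(l < 0 for l in self.l1_grid)
        ):
            raise ValueError("l1_grid must be non-empty and non-negative")


@dataclass
class SplitResult:
    """Outcome of one outer cross-validation split."""

    split_index: int
    selected_variables: tuple[str, ...]
    test_error: float
    train_error: float
    confusion: tuple[int, int, int, int]  # TP, TN, FP, FN

    def __post_init__(self) -> None:
        tp, tn, fp, fn = self.confusion
        total = tp + tn + fp + fn
        if total > 0 and abs(self.test_error - (fp + fn) / total) > 1e-12:
            raise ContractError("test_error inconsistent with confusion counts")


@dataclass
class PerMuResult:
    """All outer splits of one subset at one mu (or the single RLS entry)."""

    mu: float | None
    splits: list[SplitResult]
    mean_test_error: float
    sd_test_error: float
    median_test_error: float
    mean_train_error: float
    sd_train_error: float
    frequencies: dict[str, int]

    @classmethod
    def from_splits(
        cls, mu: float | None, splits: list[SplitResult], variables: Sequence[str]
    ) -> "PerMuResult":
        test = [s.test_error for s in splits]
        train = [s.train_error for s in splits]
        freq = {v: 0 for v in variables}
        for s in splits:
            for v in s.selected_variables:
                freq[v] += 1
        return cls(
            mu=mu,
            splits=splits,
            mean_test_error=float(np.mean(test)),
            sd_test_error=float(np.std(test)),  # population SD: one split -> 0
            median_test_error=float(median(test)),
            mean_train_error=float(np.mean(train)),
            sd_train_error=float(np.std(train)),
            frequencies=freq,
        )


@dataclass
class SelectionResult:
    """Per-subset learner output, keyed by mu index (l1l2) or "RLS"."""

    term_id: str
    technique: str
    per_mu: dict[str, PerMuResult]
    total_variables: int

    # -- serialization (ensemble sidecar) -----------------------------------

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "technique": self.technique,
            "total_variables": self.total_variables,
            "per_mu": {
                key: {
                    "mu": pm.mu,
                    "mean_test_error": pm.mean_test_error,
                    "sd_test_error": pm.sd_test_error,
                    "median_test_error": pm.median_test_error,
                    "mean_train_error": pm.mean_train_error,
                    "sd_train_error": pm.sd_train_error,
                    "frequencies": {k: pm.frequencies[k] for k in sorted(pm.frequencies)},
                    "splits": [
                        {
                            "split_index": s.split_index,
                            "selected_variables": list(s.selected_variables),
                            "test_error": s.test_error,
                            "train_error": s.train_error,
                            "confusion": list(s.confusion),
                        }
                        for s in pm.splits
                    ],
                }
                for key, pm in sorted(self.per_mu.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        per_mu = {}
        for key, pm in d["per_mu"].items():
            splits = [
                SplitResult(
                    split_index=s["split_index"],
                    selected_variables=tuple(s["selected_variables"]),
                    test_error=s["test_error"],
                    train_error=s["train_error"],
                    confusion=tuple(s["confusion"]),
                )
                for s in pm["splits"]
            ]
            per_mu[key] = PerMuResult(
                mu=pm["mu"],
                splits=splits,
                mean_test_error=pm["mean_test_error"],
                sd_test_error=pm["sd_test_error"],
                median_test_error=pm["median_test_error"],
                mean_train_error=pm["mean_train_error"],
                sd_train_error=pm["sd_train_error"],
                frequencies=dict(pm["frequencies"]),
            )
        return cls(
            term_id=d["term_id"],
            technique=d["technique"],
            per_mu=per_mu,
            total_variables=d["total_variables"],
        )


# ---------------------------------------------------------------------------
# cross-validation machinery


def task_seed(seed: int, term_id: str) -> np.random.SeedSequence:
    """Per-task seed derived from the run seed and the term identity only,
    so results never depend on task order or worker count."""
    return np.random.SeedSequence([int(seed), zlib.crc32(term_id.encode())])


def stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """K stratified folds (lists of test indices), each containing both classes."""
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (-1.0, 1.0):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {cls:+.0f} has {len(idx)} samples, fewer than k={k} folds"
            )
        perm = rng.permutation(idx)
        for j in range(k):
            folds[j].extend(perm[j::k].tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def _standardize(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns with training statistics only (no leakage)."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X_train - mean) / sd, (X_test - mean) / sd


def _majority_label(y: np.ndarray) -> float:
    """Majority training label; exact tie -> +1 (the sign-rule convention)."""
    return 1.0 if (y == 1.0).sum() >= (y == -1.0).sum() else -1.0


def _predict_two_stage(
    X_train: np.ndarray,
    y_train: np.ndarray,
    support: np.ndarray,
    X_eval: np.ndarray,
    rls_lam: float,
) -> np.ndarray:
    """RLS refit on the l1l2 support, sign-rule prediction; empty support
    predicts the majority training label."""
    if support.size == 0:
        return np.full(X_eval.shape[0], _majority_label(y_train))
    w = rls_solve(X_train[:, support], y_train, rls_lam)
    return classify(w, X_eval[:, support])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1.0) & (y_pred == 1.0)).sum())
    tn = int(((y_true == -1.0) & (y_pred == -1.0)).sum())
    fp = int(((y_true == -1.0) & (y_pred == 1.0)).sum())
    fn = int(((y_true == 1.0) & (y_pred == -1.0)).sum())
    return tp, tn, fp, fn


def _default_l1_grid(X: np.ndarray, y: np.ndarray, n_l1: int) -> np.ndarray:
    """Descending geometric grid from the full-shrinkage bound down to 1e-3 of it."""
    l1_hi = l1_max_bound(X, y)
    if l1_hi == 0.0:
        return np.zeros(1)
    return np.geomspace(l1_hi, 1e-3 * l1_hi, n_l1)


def _default_mu_values(X: np.ndarray) -> tuple[float, ...]:
    """Default correlation grid: decades from weak (near-lasso) to strong
    grouping, scaled by the mean column energy trace(X'X)/(n p) (= 1 for
    standardized columns)."""
    n, p = X.shape
    scale = float(np.trace(X.T @ X)) / (n * p) if n and p else 1.0
    return tuple(scale * m for m in (1e-2, 1e-1, 1.0))


def _inner_validation_error(
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    support: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rls_lam: float,
) -> float:
    """Mean squared validation error of the two-stage model.

    Model selection scores candidates on the continuous squared loss of
    the RLS refit rather than the thresholded classification error: the
    squared loss is the quantity the solver optimizes, and its continuous
    range avoids the massive ties a 0/1 error produces on small
    validation folds.  An empty support predicts the training-label mean.
    """
    if support.size == 0:
        score = np.full(X_val.shape[0], float(y_fit.mean()))
    else:
        w = rls_solve(X_fit[:, support], y_fit, rls_lam)
        score = X_val[:, support] @ w
    return float(np.mean((score - y_val) ** 2))


def run_l1l2_task(
    subset: TermSubset, labels: LabelVector, cfg: SolverConfig
) -> SelectionResult:
    """Full nested-CV l1l2 feature selection on one GO-term subset.

    Outer ``cfg.outer_k`` stratified folds estimate the error; for each
    outer training fold an inner ``cfg.inner_k``-fold CV over the l1 grid
    picks the l1 weight with minimal mean validation error (ties go to the
    largest weight, i.e. the sparsest model).  The selected-variable set of
    an outer split is the support of the l1l2 solution at that weight on
    the outer training data; prediction is the RLS-refit sign rule.
    Repeated for every mu; outer folds are shared across mu values.
    """
    if subset.technique != L1L2FS:
        raise ContractError(f"subset {subset.term_id} is routed to {subset.technique}")
    X_all = np.ascontiguousarray(subset.values.T)  # n x p
    y_all = labels.vector(subset.sample_ids)
    p = X_all.shape[1]
    variables = np.array(subset.probeset_ids)

    ss = task_seed(cfg.seed, subset.term_id)
    rng_outer, rng_inner = [np.random.default_rng(s) for s in ss.spawn(2)]
    outer = stratified_folds(y_all, cfg.outer_k, rng_outer)

    if cfg.mu_values is not None:
        mu_values = tuple(cfg.mu_values)
    else:
        Xs = X_all
        if cfg.standardize:
            Xs, _ = _standardize(X_all, X_all[:0])
        mu_values = _default_mu_values(Xs)

    # per outer split: standardized data, l1 grid, inner folds (shared across mu)
    prepared = []
    for o, test_idx in enumerate(outer):
        train_idx = np.setdiff1d(np.arange(len(y_all)), test_idx)
        X_tr, X_te = X_all[train_idx], X_all[test_idx]
        if cfg.standardize:
            X_tr, X_te = _standardize(X_tr, X_te)
        y_tr, y_te = y_all[train_idx], y_all[test_idx]
        grid = (
            np.asarray(cfg.l1_grid, dtype=float)[::-1]
            if cfg.l1_grid is not None
            else _default_l1_grid(X_tr, y_tr, cfg.n_l1)
        )
        grid = np.sort(grid)[::-1]  # descending for warm starts / tie-break
        inner = stratified_folds(y_tr, cfg.inner_k, rng_inner)
        prepared.append((X_tr, y_tr, X_te, y_te, grid, inner))

    per_mu: dict[str, PerMuResult] = {}
    for m_i, mu in enumerate(mu_values):
        splits: list[SplitResult] = []
        for o, (X_tr, y_tr, X_te, y_te, grid, inner) in enumerate(prepared):
            # inner CV: mean validation error per l1 (two-stage prediction)
            errs = np.zeros(len(grid))
            for val_idx in inner:
                fit_idx = np.setdiff1d(np.arange(len(y_tr)), val_idx)
                Xf, yf = X_tr[fit_idx], y_tr[fit_idx]
                Xv, yv = X_tr[val_idx], y_tr[val_idx]
                w_warm = np.zeros(p)
                for g, l1 in enumerate(grid):
                    w_warm = l1l2_solve(
                        Xf, yf, l1, mu, tol=cfg.tol, max_iter=cfg.max_iter, w0=w_warm
                    )
                    support = np.flatnonzero(w_warm)
                    errs[g] += _inner_validation_error(
                        Xf, yf, support, Xv, yv, cfg.rls_lam
                    )
            errs /= len(inner)
            best_g = int(np.argmin(errs))  # first minimum = largest l1 (sparsest)
            l1_best = float(grid[best_g])

            w = l1l2_solve(X_tr, y_tr, l1_best, mu, tol=cfg.tol, max_iter=cfg.max_iter)
            support = np.flatnonzero(w)
            pred_te = _predict_two_stage(X_tr, y_tr, support, X_te, cfg.rls_lam)
            pred_tr = _predict_two_stage(X_tr, y_tr, support, X_tr, cfg.rls_lam)
            conf = _confusion(y_te, pred_te)
            splits.append(
                SplitResult(
                    split_index=o,
                    selected_variables=tuple(sorted(variables[support])),
                    test_error=float((pred_te != y_te).mean()),
                    train_error=float((pred_tr != y_tr).mean()),
                    confusion=conf,
                )
            )
        per_mu[f"mu{m_i}"] = PerMuResult.from_splits(float(mu), splits, subset.probeset_ids)

    return SelectionResult(
        term_id=subset.term_id,
        technique=L1L2FS,
        per_mu=per_mu,
        total_variables=p,
    )


def run_rls_task(
    subset: TermSubset, labels: LabelVector, cfg: SolverConfig
) -> SelectionResult:
    """Plain RLS classification of a small subset: outer K-fold CV only.

    No inner loop and no grid; every variable counts as selected in every
    split (the final selected-or-not verdict is the significance call made
    downstream).  The result carries a single pseudo-mu entry keyed "RLS".
    """
    if subset.technique != RLS:
        raise ContractError(f"subset {subset.term_id} is routed to {subset.technique}")
    X_all = np.ascontiguousarray(subset.values.T)
    y_all = labels.vector(subset.sample_ids)

    ss = task_seed(cfg.seed, subset.term_id)
    rng_outer = np.random.default_rng(ss.spawn(2)[0])
    outer = stratified_folds(y_all, cfg.outer_k, rng_outer)

    all_vars = tuple(sorted(subset.probeset_ids))
    splits: list[SplitResult] = []
    for o, test_idx in enumerate(outer):
        train_idx = np.setdiff1d(np.arange(len(y_all)), test_idx)
        X_tr, X_te = X_all[train_idx], X_all[test_idx]
        if cfg.standardize:
            X_tr, X_te = _standardize(X_tr, X_te)
        y_tr, y_te = y_all[train_idx], y_all[test_idx]
        w = rls_solve(X_tr, y_tr, cfg.rls_lam)
        pred_te = classify(w, X_te)
        pred_tr = classify(w, X_tr)
        splits.append(
            SplitResult(
                split_index=o,
                selected_variables=all_vars,
                test_error=float((pred_te != y_te).mean()),
                train_error=float((pred_tr != y_tr).mean()),
                confusion=_confusion(y_te, pred_te),
            )
        )
    per_mu = {RLS_KEY: PerMuResult.from_splits(None, splits, subset.probeset_ids)}
    return SelectionResult(
        term_id=subset.term_id,
        technique=RLS,
        per_mu=per_mu,
        total_variables=len(subset.probeset_ids),
    )


def run_task(subset: TermSubset, labels: LabelVector, cfg: SolverConfig) -> SelectionResult:
    """Dispatch a subset to its routed technique."""
    if subset.technique == RLS:
        return run_rls_task(subset, labels, cfg)
    return run_l1l2_task(subset, labels, cfg)
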