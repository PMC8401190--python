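"""All-relevant feature selection for a continuous response.

The selection loop augments the design matrix with row-permuted shadow
copies of the candidate predictors, fits a regression random forest, and
awards a hit to every candidate whose importance strictly exceeds the best
shadow score (shadowMax).  Hit counts are tested each iteration against a
Binomial(trials, 0.5) null, Bonferroni-adjusted over the number of
candidate features, to confirm or reject predictors; undecided survivors at
the iteration cap are reported Tentative.

Three importance metrics are available:

``gini``
    total variance-impurity decrease attributed to a column, averaged over
    trees (unnormalized).
``gini_corrected``
    impurity importance debiased by the importance the forest awards to a
    row-permuted copy of the same column fitted alongside the original.
``permutation_raw``
    mean increase in out-of-bag squared error when the column is permuted
    within each tree's OOB rows (unscaled).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

CONFIRMED = "Confirmed"
REJECTED = "Rejected"
TENTATIVE = "Tentative"
UNDECIDED = "Undecided"

IMPORTANCE_METHODS = ("gini", "gini_corrected", "permutation_raw")


@dataclass
class ForestConfig:
    """Random-forest hyperparameters.

    ``features_per_split=None`` applies the regression convention of p/3
    rounded up, computed on the (possibly shadow-extended) design matrix.
    """

    n_trees: int = 500
    features_per_split: int | None = None
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_node_size < 1:
            raise ValueError("n_trees and min_node_size must be positive")
        if self.features_per_split is not None and self.features_per_split < 1:
            raise ValueError("features_per_split must be positive")

    def mtry(self, n_columns: int) -> int:
        if self.features_per_split is not None:
            return min(self.features_per_split, n_columns)
        return int(np.ceil(n_columns / 3))


@dataclass
class BorutaConfig:
    max_iter: int = 500
    alpha: float = 0.01
    adjust: str = "bonferroni"
    min_shadow: int = 5
    importance_method: str = "permutation_raw"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_shadow < 1:
            raise ValueError("min_shadow must be positive")
        if self.importance_method not in IMPORTANCE_METHODS:
            raise ValueError(f"unknown importance method {self.importance_method!r}")
        if self.adjust != "bonferroni":
            raise ValueError("only Bonferroni adjustment is supported")


@dataclass
class BorutaResult:
    """Per-feature decision trace of one selection run."""

    feature_names: list[str]
    decision: dict[str, str]
    hits: dict[str, int]
    trials: dict[str, int]
    importance_history: dict[str, list[float]]
    shadow_max_history: list[float]
    n_iterations: int = 0

    def final_importance(self, name: str) -> float:
        """Median importance over the iterations the feature participated in."""
        hist = self.importance_history[name]
        return float(np.median(hist)) if hist else float("nan")

    def features_with(self, *decisions: str) -> list[str]:
        return [f for f in self.feature_names if self.decision[f] in decisions]


def _fit_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.mtry(X.shape[1]),
        min_samples_leaf=cfg.min_node_size,
        bootstrap=True,
        random_state=int(cfg.seed) % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _impurity_importance(rf: RandomForestRegressor) -> np.ndarray:
    # unnormalized per-tree impurity decrease, averaged over trees
    return np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in rf.estimators_],
        axis=0,
    )


def _oob_permutation_importance(
    rf: RandomForestRegressor, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    n, p = X.shape
    n_boot = _get_n_samples_bootstrap(n, None, None)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    total = np.zeros(p)
    n_used = 0
    for tree in rf.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) < 2:
            continue
        Xo = X32[oob]
        yo = y[oob]
        m = len(oob)
        # bypass per-call input validation: feed the fitted Cython tree directly
        base = tree.tree_.predict(Xo).ravel()
        base_mse = np.mean((yo - base) ** 2)
        perm = np.random.default_rng(int(tree.random_state)).permutation(m)
        # one batched predict per tree: stack all single-column permutations
        big = np.broadcast_to(Xo, (p, m, p)).copy()
        for j in range(p):
            big[j, :, j] = Xo[perm, j]
        preds = tree.tree_.predict(big.reshape(p * m, p)).reshape(p, m)
        total += np.mean((yo[None, :] - preds) ** 2, axis=1) - base_mse
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return total / n_used


def rf_importance(
    X: np.ndarray, y: np.ndarray, method: str, cfg: ForestConfig
) -> np.ndarray:
    """One finite importance score per column of ``X`` under ``method``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 columns")
    if X.shape[0] != len(y) or len(y) < 10:
        raise ValueError("rows(X) must equal len(y) and be >= 10")
    if np.isnan(X).any() or not np.isfinite(y).all():
        raise ValueError("X must be complete and y finite")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if method not in IMPORTANCE_METHODS:
        raise ValueError(f"unknown importance method {method!r}")

    if method == "gini":
        return _impurity_importance(_fit_forest(X, y, cfg))
    if method == "permutation_raw":
        rf = _fit_forest(X, y, cfg)
        return _oob_permutation_importance(rf, X, y)
    # gini_corrected: fit the forest on [X | permuted(X)] and subtract each
    # column's null twin importance from its real importance.
    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    p = X.shape[1]
    Xnull = np.column_stack([X[rng.permutation(X.shape[0]), j] for j in range(p)])
    rf = _fit_forest(np.hstack([X, Xnull]), y, cfg)
    imp = _impurity_importance(rf)
    return imp[:p] - imp[p:]


def shadow_extend(
    X: np.ndarray, rng: np.random.Generator, min_shadow: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Append one row-permuted shadow per column, padding with extra
    permuted copies until at least ``min_shadow`` shadows exist.

    Returns the extended matrix and the integer indices of its shadow
    columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a nonempty 2-D matrix")
    n, p = X.shape
    shadows = [X[rng.permutation(n), j] for j in range(p)]
    j = 0
    while len(shadows) < min_shadow:
        shadows.append(X[rng.permutation(n), j % p])
        j += 1
    ext = np.hstack([X, np.column_stack(shadows)])
    return ext, np.arange(p, p + len(shadows))


@lru_cache(maxsize=1024)
def _binom_half_tails(trials: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached upper/lower tail probabilities of Binom(trials, 0.5):
    ``sf[k] = P(X >= k)``, ``cdf[k] = P(X <= k)`` for k in 0..trials."""
    k = np.arange(trials + 1)
    sf = binom.sf(k - 1, trials, 0.5)
    cdf = binom.cdf(k, trials, 0.5)
    return sf, cdf


def binomial_decision(
    hits: int, trials: int, n_features_tested: int, alpha: float
) -> str:
    """Two one-sided binomial tests at success probability 0.5 with
    Bonferroni correction over ``n_features_tested``."""
    if not 0 <= hits <= trials or trials < 1 or n_features_tested < 1:
        raise ValueError("require 0 <= hits <= trials, trials >= 1, m >= 1")
    sf, cdf = _binom_half_tails(trials)
    p_up = float(sf[hits])  # P(X >= hits)
    p_down = float(cdf[hits])  # P(X <= hits)
    if p_up * n_features_tested < alpha:
        return CONFIRMED
    if p_down * n_features_tested < alpha:
        return REJECTED
    return UNDECIDED


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    bcfg: BorutaConfig | None = None,
    fcfg: ForestConfig | None = None,
) -> BorutaResult:
    """Run the shadow-feature selection loop on ``X`` against ``y``.

    Rejected features are removed from subsequent iterations; confirmed
    features stay in the design matrix (their importance history keeps
    accruing) but are no longer tested.  The Bonferroni multiplicity is
    fixed at the number of candidate features at the start of the run.
    """
    bcfg = bcfg or BorutaConfig()
    fcfg = fcfg or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length must match X columns")
    if p < 1:
        raise ValueError("at least one candidate feature is required")

    status = {f: UNDECIDED for f in feature_names}
    hits = {f: 0 for f in feature_names}
    trials = {f: 0 for f in feature_names}
    history: dict[str, list[float]] = {f: [] for f in feature_names}
    shadow_max_history: list[float] = []
    rng = np.random.default_rng(int(fcfg.seed))
    n_iter = 0

    for _ in range(bcfg.max_iter):
        undecided = [f for f in feature_names if status[f] == UNDECIDED]
        if not undecided:
            break
        n_iter += 1
        name_to_idx = {f: j for j, f in enumerate(feature_names)}
        active = [f for f in feature_names if status[f] != REJECTED]
        idx = [name_to_idx[f] for f in active]
        Xa = X[:, idx]
        Xext, shadow_idx = shadow_extend(Xa, rng, bcfg.min_shadow)
        it_cfg = replace(fcfg, seed=int(rng.integers(2**31)))
        imp = rf_importance(Xext, y, bcfg.importance_method, it_cfg)
        shadow_max = float(np.max(imp[shadow_idx]))
        shadow_max_history.append(shadow_max)
        for k, f in enumerate(active):
            history[f].append(float(imp[k]))
        for k, f in enumerate(active):
            if status[f] != UNDECIDED:
                continue
            trials[f] += 1
            if imp[k] > shadow_max:
                hits[f] += 1
            decision = binomial_decision(hits[f], trials[f], p, bcfg.alpha)
            if decision != UNDECIDED:
                status[f] = decision

    for f in feature_names:
        if status[f] == UNDECIDED:
            status[f] = TENTATIVE

    return BorutaResult(
        feature_names=list(feature_names),
        decision=status,
        hits=hits,
        trials=trials,
        importance_history=history,
        shadow_max_history=shadow_max_history,
        n_iterations=n_iter,
    )
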