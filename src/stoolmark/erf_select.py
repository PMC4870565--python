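"""Extended Random Forest (ERF) all-relevant feature selection.

The procedure ranks OTUs by how confidently their random-forest importance
exceeds that of pure noise:

1.  The feature matrix is extended with *shadow features* — one per original
    feature, obtained by independently permuting that feature's values across
    samples, so each shadow preserves its original's marginal distribution
    while destroying any association with the response.
2.  A random forest (``n_trees``, ``mtry``) is fit on the extended matrix and
    a permutation-based variable importance measure (VIM) is recorded for
    every original and shadow feature.  This is repeated for
    ``n_stability_runs`` independent shadow draws (stability analysis),
    giving a runs x 2p VIM matrix.
3.  The shadow with the highest mean VIM is the empirical noise ceiling.
    Each original feature's per-run VIMs are compared to the best shadow's by
    a one-sided Welch t-test (alternative: feature > shadow); the *likelihood
    of relevance* is 1 - p.  By construction the best shadow itself sits at
    likelihood 0.50, and features whose likelihood exceeds the threshold
    (default 0.70) are called relevant.

VIM here is the out-of-bag permutation importance in the R randomForest
tradition: for each tree, the increase in OOB squared error (regression) or
OOB misclassification rate (classification) when a feature's OOB values are
permuted, averaged over all trees.  Trees that never split on a feature
contribute exactly zero, which lets the kernel below re-traverse only the
trees that use each feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

logger = logging.getLogger("stoolmark")

__all__ = [
    "ErfConfig",
    "VimRuns",
    "ErfResult",
    "make_shadow",
    "run_stability",
    "best_shadow",
    "relevance_likelihoods",
    "tune_mtry",
    "erf_rank",
    "SHADOW_SUFFIX",
]

SHADOW_SUFFIX = "__shadow"


@dataclass
class ErfConfig:
    """Parameters of the ERF procedure.

    ``n_trees`` and ``mtry`` default to the forest sizing used at full scale
    (25,000 trees, mtry 200, capped at the extended feature count); the
    ``scaled()`` profile (500 trees) is for desk-scale runs and tests.
    ``min_node_size`` defaults follow the R randomForest convention the
    Ntree/Mtry terminology comes from: 5 for regression, 1 for
    classification (None selects by mode).
    """

    n_trees: int = 25_000
    mtry: int = 200
    n_stability_runs: int = 20
    response_mode: str = "score_regression"
    relevance_threshold: float = 0.70
    shadow_baseline: float = 0.50
    min_node_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.n_stability_runs < 2:
            raise ValueError("n_stability_runs must be >= 2 (the t-test needs >= 2 runs)")
        if self.response_mode not in ("score_regression", "group_classification"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")
        if not (0.0 < self.relevance_threshold < 1.0):
            raise ValueError("relevance_threshold must be in (0, 1)")

    def scaled(self) -> "ErfConfig":
        """Desk-scale profile: 500 trees, everything else unchanged."""
        return replace(self, n_trees=500)


@dataclass
class VimRuns:
    """Per-run, per-feature VIM values for originals and shadows."""

    vims: pd.DataFrame  # runs x 2p, columns = feature ids then shadow ids
    feature_ids: tuple[str, ...]
    shadow_ids: tuple[str, ...]
    run_seeds: tuple[int, ...]
    response_mode: str = "score_regression"

    def __post_init__(self) -> None:
        if self.vims.isna().any().any():
            raise ValueError("VIM matrix has missing cells")


@dataclass
class ErfResult:
    """Ranked relevance table plus the best-shadow reference."""

    table: pd.DataFrame  # index feature_id; mean_vim, likelihood, rank, relevant
    best_shadow_id: str
    best_shadow_mean_vim: float
    best_shadow_likelihood: float
    relevance_threshold: float
    config: ErfConfig | None = None

    @property
    def relevant_ids(self) -> list[str]:
        return list(self.table.index[self.table["relevant"]])

    def top(self, k: int) -> list[str]:
        return list(self.table.sort_values("rank").index[:k])


# ---------------------------------------------------------------------------
# shadow extension
# ---------------------------------------------------------------------------

def make_shadow(X: np.ndarray, run_seed: int) -> np.ndarray:
    """Extend samples x p matrix to samples x 2p with permuted shadow columns.

    Column p+j is an independent random permutation of column j (one fresh
    permutation per feature), so each shadow's marginal multiset of values
    equals its original's exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to permute")
    rng = np.random.default_rng(run_seed)
    shadows = np.empty_like(X)
    for j in range(X.shape[1]):
        shadows[:, j] = X[rng.permutation(X.shape[0]), j]
    return np.hstack([X, shadows])


# ---------------------------------------------------------------------------
# OOB permutation importance kernel
# ---------------------------------------------------------------------------

def _tree_arrays(tree):
    t = tree.tree_
    if t.value.shape[2] == 1:  # regression: mean response per node
        leaf_val = t.value[:, 0, 0]
    else:  # classification: majority class per node
        leaf_val = np.argmax(t.value[:, 0, :], axis=1).astype(float)
    return t.feature, t.threshold, t.children_left, t.children_right, leaf_val


def _apply(feature, threshold, left, right, leaf_val, X):
    """Vectorized decision-path traversal -> per-row node value."""
    node = np.zeros(X.shape[0], dtype=np.int64)
    active = feature[node] >= 0
    while active.any():
        f = feature[node[active]]
        go_left = X[active, f] <= threshold[node[active]]
        nxt = np.where(go_left, left[node[active]], right[node[active]])
        node[active] = nxt
        active = feature[node] >= 0
    return leaf_val[node]


def _forest_oob_vim(forest, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                    classification: bool) -> np.ndarray:
    """R-style OOB permutation importance for every column of ``X``.

    For each tree: compute its OOB error, then for each feature used by that
    tree permute the feature's OOB values and recompute; the importance of a
    feature is the mean over *all* trees of (permuted error - error), trees
    not using the feature contributing zero.
    """
    n, p = X.shape
    totals = np.zeros(p)
    n_trees = len(forest.estimators_)
    for tree, inbag in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[inbag] = False
        m = int(oob.sum())
        if m == 0:
            continue
        arrays = _tree_arrays(tree)
        Xo = X[oob]
        yo = y[oob]
        base_pred = _apply(*arrays, Xo)
        if classification:
            base_err = np.mean(base_pred != yo)
        else:
            base_err = np.mean((base_pred - yo) ** 2)
        used = np.unique(arrays[0][arrays[0] >= 0])
        if used.size == 0:
            continue
        perm = rng.permutation(m)
        k = used.size
        # one traversal for all used features: block i is X with feature
        # used[i]'s OOB values permuted
        Xbatch = np.tile(Xo, (k, 1))
        for i, j in enumerate(used):
            Xbatch[i * m:(i + 1) * m, j] = Xo[perm, j]
        preds = _apply(*arrays, Xbatch).reshape(k, m)
        if classification:
            errs = np.mean(preds != yo[None, :], axis=1)
        else:
            errs = np.mean((preds - yo[None, :]) ** 2, axis=1)
        totals[used] += errs - base_err
    return totals / n_trees


# ---------------------------------------------------------------------------
# stability analysis
# ---------------------------------------------------------------------------

def _run_seeds(seed: int, n_runs: int) -> tuple[int, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(int(s) % (2**31) for s in ss.generate_state(n_runs))


def run_stability(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    config: ErfConfig,
) -> VimRuns:
    """Repeated shadow-extension + forest fits; the VIM matrix across runs.

    Run r uses a seed derived from ``config.seed`` and r, so runs are
    mutually independent but the whole analysis is reproducible.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = tuple(str(c) for c in X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_ids = tuple(f"f{j}" for j in range(Xv.shape[1]))
    yv = np.asarray(pd.Series(y).to_numpy())
    if Xv.shape[0] < 5:
        raise ValueError(f"too few samples for ERF: n={Xv.shape[0]} < 5")
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError("X and y have different numbers of samples")

    classification = config.response_mode == "group_classification"
    if classification:
        classes, yv = np.unique(yv, return_inverse=True)
        yv = yv.astype(float)
        if classes.size < 2:
            raise ValueError("classification response has a single class")
    else:
        yv = yv.astype(float)
        if not np.isfinite(yv).all():
            raise ValueError("non-finite response values")

    p = Xv.shape[1]
    mtry = min(config.mtry, 2 * p)
    leaf = config.min_node_size if config.min_node_size is not None else (1 if classification else 5)
    shadow_ids = tuple(f + SHADOW_SUFFIX for f in feature_ids)
    seeds = _run_seeds(config.seed, config.n_stability_runs)

    rows = np.empty((config.n_stability_runs, 2 * p))
    for r, rs in enumerate(seeds):
        Xext = make_shadow(Xv, rs)
        if classification:
            forest = RandomForestClassifier(
                n_estimators=config.n_trees, max_features=mtry,
                min_samples_leaf=leaf, bootstrap=True, random_state=rs, n_jobs=1,
            )
        else:
            forest = RandomForestRegressor(
                n_estimators=config.n_trees, max_features=mtry,
                min_samples_leaf=leaf, bootstrap=True, random_state=rs, n_jobs=1,
            )
        forest.fit(Xext, yv)
        vim_rng = np.random.default_rng(rs + 1)
        rows[r] = _forest_oob_vim(forest, Xext, yv, vim_rng, classification)
    vims = pd.DataFrame(rows, columns=list(feature_ids) + list(shadow_ids))
    return VimRuns(
        vims=vims, feature_ids=feature_ids, shadow_ids=shadow_ids,
        run_seeds=seeds, response_mode=config.response_mode,
    )


def best_shadow(v: VimRuns) -> str:
    """The shadow feature with maximal mean VIM; ties break lexicographically."""
    means = v.vims[list(v.shadow_ids)].mean(axis=0)
    top = means.max()
    candidates = sorted(means.index[means == top])
    return candidates[0]


def _one_sided_likelihood(feat_vims: np.ndarray, shadow_vims: np.ndarray) -> float:
    """1 - p of the one-sided Welch t-test (alternative: feature > shadow)."""
    if np.var(feat_vims) == 0 and np.var(shadow_vims) == 0:
        d = feat_vims.mean() - shadow_vims.mean()
        return 0.5 if d == 0 else (1.0 if d > 0 else 0.0)
    t = stats.ttest_ind(feat_vims, shadow_vims, equal_var=False, alternative="greater")
    return float(1.0 - t.pvalue)


def relevance_likelihoods(v: VimRuns, config: ErfConfig | None = None) -> ErfResult:
    """Likelihood of relevance per original feature, ranked.

    Each feature's per-run VIMs are tested against the best shadow's per-run
    VIMs (one-sided Welch, alternative feature > shadow); likelihood = 1 - p.
    Ranks sort by likelihood descending, ties by mean VIM then feature id;
    the relevant flag uses a strict ``likelihood > threshold``.
    """
    cfg = config or ErfConfig()
    bs = best_shadow(v)
    shadow_vims = v.vims[bs].to_numpy()
    rows = []
    for f in v.feature_ids:
        fv = v.vims[f].to_numpy()
        rows.append((f, fv.mean(), _one_sided_likelihood(fv, shadow_vims)))
    table = pd.DataFrame(rows, columns=["feature_id", "mean_vim", "likelihood"]).set_index("feature_id")
    order = table.sort_values(
        by=["likelihood", "mean_vim", "feature_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).index
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    table["relevant"] = table["likelihood"] > cfg.relevance_threshold
    table = table.loc[order]
    return ErfResult(
        table=table,
        best_shadow_id=bs,
        best_shadow_mean_vim=float(shadow_vims.mean()),
        best_shadow_likelihood=_one_sided_likelihood(shadow_vims, shadow_vims),
        relevance_threshold=cfg.relevance_threshold,
        config=config,
    )


def erf_rank(
    X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series, config: ErfConfig
) -> ErfResult:
    """Full ERF: stability runs then likelihood ranking."""
    return relevance_likelihoods(run_stability(X, y, config), config)


# ---------------------------------------------------------------------------
# parameter selection
# ---------------------------------------------------------------------------

def tune_mtry(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    grid: list[int],
    config: ErfConfig,
) -> int:
    """Out-of-bag grid search for mtry; ties go to the smallest value.

    Fits one forest per candidate (at ``config.n_trees``) and returns the
    mtry with minimal OOB error (mean squared error for regression,
    misclassification rate for classification).
    """
    if not grid:
        raise ValueError("mtry grid must be non-empty")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if any(g > Xv.shape[1] or g < 1 for g in grid):
        raise ValueError("every grid value must be in [1, n_features]")
    yv = np.asarray(pd.Series(y).to_numpy())
    classification = config.response_mode == "group_classification"
    leaf = config.min_node_size if config.min_node_size is not None else (1 if classification else 5)
    errors: dict[int, float] = {}
    for m in grid:
        if classification:
            forest = RandomForestClassifier(
                n_estimators=config.n_trees, max_features=m, min_samples_leaf=leaf,
                oob_score=True, bootstrap=True, random_state=config.seed, n_jobs=1,
            )
            forest.fit(Xv, yv)
            errors[m] = 1.0 - float(forest.oob_score_)
        else:
            forest = RandomForestRegressor(
                n_estimators=config.n_trees, max_features=m, min_samples_leaf=leaf,
                oob_score=True, bootstrap=True, random_state=config.seed, n_jobs=1,
            )
            forest.fit(Xv, yv.astype(float))
            errors[m] = float(np.mean((forest.oob_prediction_ - yv.astype(float)) ** 2))
        logger.info("tune_mtry: mtry=%d oob_error=%.5f", m, errors[m])
    best = min(errors, key=lambda m: (errors[m], m))
    return best
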