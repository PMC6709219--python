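"""Per-timepoint decoding: standardize → L1 feature selection → logistic.

At every timepoint the pipeline is cross-validated with stratified
5-fold splits: features are z-scored on the training fold (statistics
then applied to the test fold), a sparse feature set is chosen by a
cross-validated Lasso (4 stratified inner folds over a logarithmic
penalty path), a logistic regression with C = 1 is fit on the selected
features, and the test fold is scored by ROC-AUC on the model's
continuous decision values.  The fold assignment is computed once per
dataset from a seed and reused across timepoints (and, by default,
across label permutations), so runs are exactly reproducible.

Two interchangeable engines solve the two model fits.  ``"fast"``
(default) is a compact coordinate-descent / damped-Newton implementation
compiled with numba, sized for the permutation test's inner loop where
the pipeline is refit hundreds of thousands of times on small matrices;
``"sklearn"`` routes the same numerics through
:class:`sklearn.linear_model.Lasso` paths and
:class:`sklearn.linear_model.LogisticRegression`.  The engines optimize
the same objectives on the same penalty grids and are held equivalent by
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import _engine

__all__ = [
    "PipelineConfig",
    "DecodingResult",
    "PatternMap",
    "ClusterPatterns",
    "standardize",
    "select_features_l1",
    "decode_over_time",
    "decode_matrix",
    "roc_auc",
    "haufe_patterns",
    "cluster_patterns",
    "stratified_folds",
]

Folds = list[tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class PipelineConfig:
    """Classifier-pipeline settings.

    ``n_alphas`` / ``alpha_eps`` define the logarithmic Lasso penalty
    path (``n_alphas`` values from the data-derived maximum down to
    ``alpha_eps`` times it).  Defaults mirror the standard pipeline:
    5 stratified outer folds, 4 stratified selector folds, logistic
    C = 1, ROC-AUC scoring.  ``engine`` selects the model-fit backend
    (see module docstring).
    """

    outer_folds: int = 5
    selector_folds: int = 4
    logistic_C: float = 1.0
    n_alphas: int = 25
    alpha_eps: float = 1e-2
    seed: int = 0
    engine: str = "fast"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.selector_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.logistic_C <= 0:
            raise ValueError("logistic_C must be positive")
        if self.n_alphas < 1:
            raise ValueError("n_alphas must be >= 1")
        if self.engine not in ("fast", "sklearn"):
            raise ValueError(f"engine must be 'fast' or 'sklearn', got {self.engine!r}")


@dataclass
class DecodingResult:
    """Time-resolved decoding scores.

    ``fold_aucs`` is (n_folds, n_times); ``mean_auc`` its fold mean and
    ``fold_sd`` the sample SD across folds.  ``selected`` holds, per
    timepoint, one boolean feature mask per fold.  ``folds`` records the
    exact (train, test) row indices so a rerun — or a label permutation —
    can reuse the assignment.
    """

    times: np.ndarray
    mean_auc: np.ndarray
    fold_aucs: np.ndarray
    fold_sd: np.ndarray
    selected: list[list[np.ndarray]]
    folds: Folds
    config: PipelineConfig


@dataclass
class PatternMap:
    """Haufe activation pattern with top/bottom fraction masks."""

    pattern: np.ndarray
    top_mask: np.ndarray
    bottom_mask: np.ndarray
    top_frac: float = 0.05


@dataclass
class ClusterPatterns:
    """Patterns aggregated over the folds × timepoints of a cluster.

    ``mean`` is the fold/timepoint-average pattern with masks taken on
    the average; ``top_union``/``bottom_union`` are the unions of the
    per-fit masks (useful for localizing an effect: any feature a fold
    ranked in its extreme 5% at any cluster timepoint).
    """

    mean: PatternMap
    top_union: np.ndarray
    bottom_union: np.ndarray


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> Folds:
    """Seeded stratified fold assignment keyed to sample identity.

    Each class's rows are shuffled with the seeded generator and dealt
    into folds as evenly as possible, so every fold's class ratio equals
    the data set's within rounding.  Both pipeline engines share this
    assignment.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need at least one per "
            f"fold ({n_folds} folds)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n_folds,)))
    fold_of = np.empty(len(y), dtype=int)
    for cls in classes:
        rows = np.flatnonzero(y == cls)
        rows = rows[rng.permutation(len(rows))]
        # deal class rows round-robin across folds
        fold_of[rows] = np.arange(len(rows)) % n_folds
    folds: Folds = []
    for f in range(n_folds):
        te = np.flatnonzero(fold_of == f)
        tr = np.flatnonzero(fold_of != f)
        folds.append((tr, te))
    return folds


def standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score features on the training set; apply the same map to the test set.

    Population SD convention (ddof = 0).  Zero-variance features are
    mapped to 0 in both sets rather than dividing by zero.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("standardize needs at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    train_z = (train - mean) / sd_safe
    test_z = (test - mean) / sd_safe
    train_z[:, zero] = 0.0
    test_z[:, zero] = 0.0
    return train_z, test_z


def _alpha_grid(
    X: np.ndarray, y_centered: np.ndarray, n_alphas: int, alpha_eps: float
) -> np.ndarray:
    """Descending logarithmic penalty path from the data-derived maximum."""
    alpha_max = np.abs(X.T @ y_centered).max() / len(y_centered)
    if alpha_max <= 0:
        alpha_max = 1.0
    if n_alphas == 1:
        return np.array([alpha_max])
    return np.geomspace(alpha_max, alpha_max * alpha_eps, n_alphas)


def _lasso_path_sklearn(X: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    from sklearn.linear_model import lasso_path

    with warnings.catch_warnings():
        # the dense end of the path on noise-dominated folds legitimately
        # stops at max_iter; the selected sparse end is converged
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(X, yc, alphas=alphas)
    return coefs


def _lasso_path_for(engine: str):
    return _engine.lasso_path_gram if engine == "fast" else _lasso_path_sklearn


def select_features_l1(
    train: np.ndarray,
    labels: np.ndarray,
    selector_folds: int = 4,
    seed: int = 0,
    n_alphas: int = 25,
    alpha_eps: float = 1e-2,
    engine: str = "fast",
) -> np.ndarray:
    """Sparse feature mask from a cross-validated Lasso on ±1-coded labels.

    The penalty is chosen by stratified CV over a descending logarithmic
    path (ties broken toward the sparser, larger penalty); the mask is
    the set of features with nonzero coefficients at that penalty refit
    on the full training set.  If that mask is empty — e.g. the CV picks
    the maximal penalty because no feature predicts the labels — the
    fallback keeps the single largest-|coefficient| feature from the
    densest penalty of the path, so the downstream classifier is always
    defined.
    """
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"feature selection needs exactly 2 classes, got {classes}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    path = _lasso_path_for(engine)

    alphas = _alpha_grid(train, y - y.mean(), n_alphas, alpha_eps)
    # degrade gracefully on very small training folds: stratified CV needs
    # at least one sample of each class per fold
    min_class = int(np.bincount((y > 0).astype(int)).min())
    if min_class < 2:
        coefs = path(train, y - y.mean(), alphas)
        mask = np.zeros(train.shape[1], dtype=bool)
        mask[int(np.argmax(np.abs(coefs[:, -1])))] = True
        return mask
    folds = stratified_folds(y, min(selector_folds, min_class), seed)
    val_mse = np.zeros(len(alphas))
    for tr, te in folds:
        y_tr = y[tr]
        offset = y_tr.mean()
        coefs = path(train[tr], y_tr - offset, alphas)
        pred = train[te] @ coefs + offset  # (n_val, n_alphas)
        val_mse += ((pred - y[te][:, np.newaxis]) ** 2).mean(axis=0)
    best = int(np.argmin(val_mse))  # first minimum = largest alpha = sparsest

    coefs = path(train, y - y.mean(), alphas)
    mask = coefs[:, best] != 0
    if not mask.any():
        dense = coefs[:, -1]  # densest (smallest) penalty
        mask = np.zeros(train.shape[1], dtype=bool)
        mask[int(np.argmax(np.abs(dense)))] = True
    return mask


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties ½).

    Exactly the pairwise count with tied pairs contributing one half;
    computed directly for small inputs and via midranks for large ones.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    if len(scores) <= 64:
        sp = scores[pos][:, np.newaxis]
        sn = scores[~pos][np.newaxis, :]
        wins = (sp > sn).sum() + 0.5 * (sp == sn).sum()
        return float(wins / (n_pos * n_neg))
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _fit_logistic(X: np.ndarray, y01: np.ndarray, C: float, engine: str):
    """Fit l2-logistic (unpenalized intercept); return (weights, intercept)."""
    if engine == "fast":
        return _engine.logistic_newton(X, np.where(y01 == np.max(y01), 1.0, -1.0), C)
    from sklearn.linear_model import LogisticRegression

    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    model.fit(X, y01)
    return model.coef_.ravel(), float(model.intercept_[0])


def _fit_fold(
    X: np.ndarray,
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    config: PipelineConfig,
    collect_model: bool = False,
):
    """One fold of the pipeline at one timepoint.

    Returns (auc, mask) and, with ``collect_model``, also the logistic
    weights mapped back to full feature space and the standardized
    training matrix (for pattern computation).

    A fold whose train or test rows carry only one class (possible under
    label permutation with a reused fold assignment) has no defined
    score and returns ``auc = NaN``; aggregations skip it.
    """
    if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
        return np.nan, np.zeros(X.shape[1], dtype=bool), None, None
    train_z, test_z = standardize(X[tr], X[te])
    mask = select_features_l1(
        train_z,
        y[tr],
        selector_folds=config.selector_folds,
        seed=config.seed,
        n_alphas=config.n_alphas,
        alpha_eps=config.alpha_eps,
        engine=config.engine,
    )
    w, b = _fit_logistic(train_z[:, mask], y[tr], config.logistic_C, config.engine)
    scores = test_z[:, mask] @ w + b
    auc = roc_auc(scores, y[te])
    if not collect_model:
        return auc, mask, None, None
    w_full = np.zeros(X.shape[1])
    w_full[mask] = w
    return auc, mask, w_full, train_z


def _nanstd_sample(fold_aucs: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(fold_aucs, axis=0, ddof=1)


def decode_matrix(
    X: np.ndarray, y: np.ndarray, folds: Folds, config: PipelineConfig
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cross-validated pipeline on a single (rows × features) matrix.

    Returns per-fold ROC-AUC scores and the per-fold selected-feature
    masks.  This is the unit the permutation test reruns under shuffled
    labels.
    """
    aucs = np.empty(len(folds))
    masks: list[np.ndarray] = []
    for i, (tr, te) in enumerate(folds):
        auc, mask, _, _ = _fit_fold(X, y, tr, te, config)
        aucs[i] = auc
        masks.append(mask)
    return aucs, masks


def decode_over_time(
    dataset,
    config: PipelineConfig,
    timepoints: Sequence[int] | None = None,
) -> DecodingResult:
    """Run the cross-validated pipeline independently at each timepoint.

    ``timepoints`` selects a subset of time indices (default: all).
    Fully deterministic given ``config.seed``: the stratified outer fold
    assignment is drawn once and reused at every timepoint.
    """
    y = dataset.y
    folds = stratified_folds(y, config.outer_folds, config.seed)
    if timepoints is None:
        timepoints = np.arange(dataset.n_times)
    timepoints = np.asarray(timepoints, dtype=int)

    fold_aucs = np.empty((len(folds), len(timepoints)))
    selected: list[list[np.ndarray]] = []
    for j, ti in enumerate(timepoints):
        aucs, masks = decode_matrix(dataset.X[:, :, ti], y, folds, config)
        fold_aucs[:, j] = aucs
        selected.append(masks)
    return DecodingResult(
        times=dataset.times[timepoints],
        mean_auc=np.nanmean(fold_aucs, axis=0),
        fold_aucs=fold_aucs,
        fold_sd=_nanstd_sample(fold_aucs),
        selected=selected,
        folds=folds,
        config=config,
    )


def haufe_patterns(
    weights: np.ndarray, train: np.ndarray, top_frac: float = 0.05
) -> PatternMap:
    """Transform linear-model weights into an activation pattern.

    For a linear decoder s = Xw, the corresponding forward pattern is
    a = Cov(X) w / Var(s): the signal each feature would carry per unit
    of the model's decision value.  Unlike raw weights, large |a| does
    mean large class-related signal.  ``top_mask``/``bottom_mask`` flag
    the highest/lowest ``top_frac`` of features (count rounded, at
    least 1).
    """
    weights = np.asarray(weights, dtype=float)
    train = np.asarray(train, dtype=float)
    cov = np.atleast_2d(np.cov(train, rowvar=False, ddof=1))
    pattern = cov @ weights
    var_s = float(weights @ cov @ weights)
    if var_s <= 0:
        raise ValueError("decision-value variance is zero; pattern undefined")
    pattern = pattern / var_s
    top, bottom = _extreme_masks(pattern, top_frac)
    return PatternMap(pattern=pattern, top_mask=top, bottom_mask=bottom, top_frac=top_frac)


def _extreme_masks(pattern: np.ndarray, top_frac: float) -> tuple[np.ndarray, np.ndarray]:
    n = len(pattern)
    k = max(1, int(round(top_frac * n)))
    order = np.argsort(pattern)
    top = np.zeros(n, dtype=bool)
    bottom = np.zeros(n, dtype=bool)
    top[order[-k:]] = True
    bottom[order[:k]] = True
    return top, bottom


def cluster_patterns(
    dataset,
    timepoints: Sequence[int],
    config: PipelineConfig,
    top_frac: float = 0.05,
) -> ClusterPatterns:
    """Haufe patterns pooled over folds and the timepoints of a cluster.

    Refits the pipeline at each timepoint (same fold assignment as
    :func:`decode_over_time`), computes one pattern per fold × timepoint,
    and aggregates: the mean pattern with masks on the mean, plus the
    union of per-fit top/bottom masks.
    """
    y = dataset.y
    folds = stratified_folds(y, config.outer_folds, config.seed)
    n_feat = dataset.n_features
    acc = np.zeros(n_feat)
    top_union = np.zeros(n_feat, dtype=bool)
    bottom_union = np.zeros(n_feat, dtype=bool)
    n_fits = 0
    for ti in timepoints:
        X = dataset.X[:, :, int(ti)]
        for tr, te in folds:
            _, _, w_full, train_z = _fit_fold(X, y, tr, te, config, collect_model=True)
            if not np.any(w_full):
                continue  # selection degenerate in this fold; nothing to localize
            pm = haufe_patterns(w_full, train_z, top_frac=top_frac)
            acc += pm.pattern
            top_union |= pm.top_mask
            bottom_union |= pm.bottom_mask
            n_fits += 1
    if n_fits == 0:
        raise ValueError("no fold produced a usable model; cannot form patterns")
    mean_pattern = acc / n_fits
    top, bottom = _extreme_masks(mean_pattern, top_frac)
    mean = PatternMap(pattern=mean_pattern, top_mask=top, bottom_mask=bottom, top_frac=top_frac)
    return ClusterPatterns(mean=mean, top_union=top_union, bottom_union=bottom_union)
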