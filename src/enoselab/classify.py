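"""Four discrimination procedures with cross-validated reporting.

* method A — PCA on concatenated representative curves, then LDA/QDA
* method B — PCA on extracted features, then LDA
* method C — forward-stepwise discriminant analysis (Wilks' lambda partial F)
* method D — RBF-SVM: (C, sigma) grid search, then greedy forward index
  selection by cross-validated accuracy, recording a cumulative
  sensitivity/specificity/accuracy trace

The RBF kernel convention is ``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))``;
the scikit-learn ``gamma`` convention is ``gamma = 1 / (2 sigma^2)``.

Selection (methods C and D) runs on the full dataset by default, matching
the original protocol; ``nested=True`` re-runs selection inside every
training fold, which is the unbiased variant and the one that stays at
chance level under a null effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "ClassifierConfig",
    "SelectionTrace",
    "evaluate",
    "pca_project",
    "da_classify",
    "stepwise_select",
    "stepwise_da",
    "svm_grid_search",
    "greedy_svm_selection",
    "nested_greedy_svm_eval",
    "nested_stepwise_da_eval",
    "cv_splits",
    "sigma_to_gamma",
]

POSITIVE_DEFAULT = "B"

META_COLUMNS = ("subject_id", "group")


def _default_c_grid() -> tuple[float, ...]:
    # logarithmic, 7 points per decade over 1..1000
    return tuple(np.logspace(0.0, 3.0, 22))


def _default_sigma_grid() -> tuple[float, ...]:
    # log below 1, linear 2..50 above
    low = np.geomspace(0.1, 1.0, 5)
    high = np.arange(2.0, 52.0, 2.0)
    return tuple(np.concatenate([low, high]))


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with the derived proportions."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def evaluate(y_true, y_pred, positive: str = POSITIVE_DEFAULT) -> EvalResult:
    """Confusion counts of aligned label sequences, ``positive`` = cases."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = set(np.unique(y_true))
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} absent from y_true")
    unseen = set(np.unique(y_pred)) - classes
    if unseen:
        raise ValueError(f"predictions contain unseen labels: {sorted(unseen)}")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return EvalResult(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings shared by the four discrimination methods.

    ``cv`` is ``"loo"`` or ``("stratified", k)``.  ``C`` / ``sigma`` may be
    preset to skip the grid search.  ``error_margin_note`` is carried for
    reporting only; it is not a solver parameter.
    """

    method: str = "D"
    n_components: int = 2
    C_grid: tuple[float, ...] = field(default_factory=_default_c_grid)
    sigma_grid: tuple[float, ...] = field(default_factory=_default_sigma_grid)
    C: float | None = None
    sigma: float | None = None
    max_indices: int = 10
    cv: object = "loo"
    seed: int = 0
    sda_entry_alpha: float = 0.05
    sda_removal_alpha: float = 0.10
    standardize: bool = True
    positive: str = POSITIVE_DEFAULT
    error_margin_note: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("A", "B", "C", "D"):
            raise ValueError("method: must be one of A, B, C, D")
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid: must be non-empty and strictly positive")
        if not self.sigma_grid or any(s <= 0 for s in self.sigma_grid):
            raise ValueError("sigma_grid: must be non-empty and strictly positive")
        if self.max_indices < 1:
            raise ValueError("max_indices: must be >= 1")


def sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma**2)


def cv_splits(y, cv="loo", seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold index pairs for leave-one-out or seeded stratified k-fold."""
    y = np.asarray(y)
    n = y.size
    if cv == "loo":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    if isinstance(cv, (tuple, list)) and len(cv) == 2 and cv[0] == "stratified":
        skf = StratifiedKFold(n_splits=int(cv[1]), shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros((n, 1)), y)]
    raise ValueError(f"unknown cv scheme {cv!r}")


def _standardize_train_apply(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


# ---------------------------------------------------------------------------
# PCA and discriminant analysis


def pca_project(X: np.ndarray, n_components: int, standardize: bool = False):
    """Principal-component scores and explained-variance shares.

    Raises if ``n_components`` exceeds the rank of the centered data.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if standardize:
        X, _ = _standardize_train_apply(X, X[:0])
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def _fit_da(Xtr, ytr, kind: str):
    if kind == "linear":
        model = LinearDiscriminantAnalysis()
    elif kind == "quadratic":
        model = QuadraticDiscriminantAnalysis()
    else:
        raise ValueError("kind: must be 'linear' or 'quadratic'")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model.fit(Xtr, ytr)
            bad = any("collinear" in str(w.message).lower() for w in caught)
        except np.linalg.LinAlgError:
            bad = True
    if bad:
        # singular within-class covariance: shrink and refit
        logger.warning("singular covariance in %s DA; falling back to shrinkage", kind)
        if kind == "linear":
            model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            model = QuadraticDiscriminantAnalysis(reg_param=1e-3)
        model.fit(Xtr, ytr)
    return model


def da_classify(
    X,
    y,
    kind: str = "linear",
    cv="loo",
    seed: int = 0,
    positive: str = POSITIVE_DEFAULT,
    pca_components: int | None = None,
    standardize: bool = False,
) -> EvalResult:
    """Cross-validated LDA/QDA; optional per-fold standardization and PCA.

    All preprocessing is refit on each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    preds = np.empty(y.size, dtype=y.dtype)
    for tr, te in cv_splits(y, cv, seed):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("training fold lost a class; use stratified folds")
        Xtr, Xte = X[tr], X[te]
        if standardize:
            Xtr, Xte = _standardize_train_apply(Xtr, Xte)
        if pca_components is not None:
            pca = PCA(n_components=pca_components)
            Xtr = pca.fit_transform(Xtr)
            Xte = pca.transform(Xte)
        model = _fit_da(Xtr, y[tr], kind)
        preds[te] = model.predict(Xte)
    return evaluate(y, preds, positive)


# ---------------------------------------------------------------------------
# Stepwise discriminant analysis (Wilks' lambda partial F)


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """det(within scatter) / det(total scatter); 0 < lambda <= 1."""
    mu = X.mean(axis=0)
    T = (X - mu).T @ (X - mu)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        d = Xg - Xg.mean(axis=0)
        W += d.T @ d
    sign_t, ld_t = np.linalg.slogdet(T)
    sign_w, ld_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        return float("nan")  # singular scatter: caller skips this candidate
    return float(np.exp(ld_w - ld_t))


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    max_selected: int | None = None,
) -> list[str]:
    """Forward-stepwise variable entry (with removal) for two-group DA.

    At each step the candidate minimizing Wilks' lambda enters if its
    partial-F p-value is below ``entry_alpha``; entered variables whose
    F-to-remove p-value exceeds ``removal_alpha`` are dropped again.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    g = np.unique(y).size
    if g != 2:
        raise ValueError("stepwise_select expects exactly 2 groups")
    cols = {name: X[:, j] for j, name in enumerate(names)}
    selected: list[str] = []

    def lam(subset: list[str]) -> float:
        if not subset:
            return 1.0
        return _wilks_lambda(np.column_stack([cols[v] for v in subset]), y)

    def partial_f(lam_small: float, lam_big: float, p_small: int):
        df2 = n - g - p_small
        if df2 <= 0 or not np.isfinite(lam_big) or lam_big <= 0:
            return None
        F = df2 / (g - 1) * (lam_small / lam_big - 1.0)
        return F, f_dist.sf(F, g - 1, df2)

    for _ in range(2 * len(names)):
        lam_cur = lam(selected)
        best = None
        for v in sorted(set(names) - set(selected)):
            res = partial_f(lam_cur, lam(selected + [v]), len(selected))
            if res is None:
                continue
            if best is None or res[0] > best[1]:
                best = (v, res[0], res[1])
        if best is None or best[2] >= entry_alpha:
            break
        selected.append(best[0])
        # removal pass
        changed = True
        while changed and len(selected) > 1:
            changed = False
            worst = None
            lam_full = lam(selected)
            for v in selected:
                rest = [u for u in selected if u != v]
                res = partial_f(lam(rest), lam_full, len(rest))
                if res is None:
                    continue
                if worst is None or res[1] > worst[1]:
                    worst = (v, res[1])
            if worst is not None and worst[1] > removal_alpha:
                selected.remove(worst[0])
                changed = True
        if max_selected is not None and len(selected) >= max_selected:
            break
    return selected


def _feature_matrix(features: pd.DataFrame):
    names = [c for c in features.columns if c not in META_COLUMNS]
    X = features[names].to_numpy(float)
    y = features["group"].to_numpy()
    return X, y, names


def _chance_predictions(y: np.ndarray, splits) -> np.ndarray:
    preds = np.empty(y.size, dtype=y.dtype)
    for tr, te in splits:
        vals, counts = np.unique(y[tr], return_counts=True)
        preds[te] = vals[np.argmax(counts)]
    return preds


def stepwise_da(features: pd.DataFrame, config: ClassifierConfig) -> tuple[list[str], EvalResult]:
    """Stepwise selection on the full table, then cross-validated LDA."""
    X, y, names = _feature_matrix(features)
    selected = stepwise_select(
        X, y, names, config.sda_entry_alpha, config.sda_removal_alpha
    )
    splits = cv_splits(y, config.cv, config.seed)
    if not selected:
        logger.warning("stepwise DA selected no feature; reporting chance-level result")
        return [], evaluate(y, _chance_predictions(y, splits), config.positive)
    idx = [names.index(v) for v in selected]
    result = da_classify(
        X[:, idx], y, kind="linear", cv=config.cv, seed=config.seed,
        positive=config.positive,
    )
    return selected, result


def nested_stepwise_da_eval(features: pd.DataFrame, config: ClassifierConfig) -> EvalResult:
    """Unbiased variant: stepwise selection redone inside every training fold."""
    X, y, names = _feature_matrix(features)
    preds = np.empty(y.size, dtype=y.dtype)
    for tr, te in cv_splits(y, config.cv, config.seed):
        sel = stepwise_select(
            X[tr], y[tr], names, config.sda_entry_alpha, config.sda_removal_alpha
        )
        if not sel:
            vals, counts = np.unique(y[tr], return_counts=True)
            preds[te] = vals[np.argmax(counts)]
            continue
        idx = [names.index(v) for v in sel]
        model = _fit_da(X[np.ix_(tr, idx)], y[tr], "linear")
        preds[te] = model.predict(X[np.ix_(te, idx)])
    return evaluate(y, preds, config.positive)


# ---------------------------------------------------------------------------
# RBF-SVM: grid search and greedy forward selection
#
# For feature subsets the squared distance is additive across features, so
# per-feature pairwise squared-distance matrices are precomputed once and
# candidate kernels assembled by summation.


def _pairwise_sqdist_per_feature(X: np.ndarray) -> np.ndarray:
    """Stack of (n, n) squared-distance matrices, one per feature column."""
    diff = X[:, None, :] - X[None, :, :]
    return np.moveaxis(diff**2, 2, 0)


def _probe_fast_libsvm():
    """Direct libsvm bindings skip sklearn's per-fit validation overhead.

    Probed once against the public SVC on a toy problem; any discrepancy or
    API change disables the fast path (the slow path is always correct).
    """
    try:
        from sklearn.svm import _libsvm

        _libsvm.set_verbosity_wrap(0)
        rng = np.random.RandomState(0)
        X = rng.normal(size=(12, 2))
        yy = np.array([0.0] * 6 + [1.0] * 6)
        X[6:] += 2.0
        K = np.ascontiguousarray(X @ X.T)
        out = _libsvm.fit(K, yy, svm_type=0, kernel="precomputed", C=1.0)
        pred = _libsvm.predict(K, *out[:7], svm_type=0, kernel="precomputed")
        ref = SVC(C=1.0, kernel="precomputed").fit(K, yy).predict(K)
        if np.array_equal(pred, ref):
            return _libsvm
    except Exception:  # pragma: no cover - depends on sklearn internals
        pass
    logger.warning("fast libsvm path unavailable; using sklearn SVC throughout")
    return None


_FAST_LIBSVM = _probe_fast_libsvm()


def _svm_cv_predict_precomputed(K, y, C, splits) -> np.ndarray:
    preds = np.empty(y.size, dtype=y.dtype)
    classes, codes = np.unique(y, return_inverse=True)
    codes = codes.astype(np.float64)
    for tr, te in splits:
        if len(np.unique(codes[tr])) < 2:
            logger.warning("single-class training fold skipped in SVM CV")
            preds[te] = y[tr][0]
            continue
        Ktr = np.ascontiguousarray(K[np.ix_(tr, tr)])
        Kte = np.ascontiguousarray(K[np.ix_(te, tr)])
        if _FAST_LIBSVM is not None:
            out = _FAST_LIBSVM.fit(Ktr, codes[tr], svm_type=0, kernel="precomputed", C=float(C))
            p = _FAST_LIBSVM.predict(Kte, *out[:7], svm_type=0, kernel="precomputed")
            preds[te] = classes[p.astype(int)]
        else:
            clf = SVC(C=C, kernel="precomputed")
            clf.fit(Ktr, y[tr])
            preds[te] = clf.predict(Kte)
    return preds


def svm_grid_search(
    features: pd.DataFrame, config: ClassifierConfig
) -> tuple[float, float, float]:
    """Best ``(C, sigma, cv_accuracy)`` on the full candidate set.

    Ties are broken toward smaller C, then smaller sigma.
    """
    X, y, _ = _feature_matrix(features)
    if config.standardize:
        X, _ = _standardize_train_apply(X, X[:0])
    D = _pairwise_sqdist_per_feature(X).sum(axis=0)
    splits = cv_splits(y, config.cv, config.seed)
    kernels = {s: np.exp(-D / (2.0 * s**2)) for s in sorted(config.sigma_grid)}
    best = None
    for C in sorted(config.C_grid):
        for sigma in sorted(config.sigma_grid):
            preds = _svm_cv_predict_precomputed(kernels[sigma], y, C, splits)
            acc = float(np.mean(preds == y))
            if best is None or acc > best[2]:
                best = (float(C), float(sigma), acc)
    return best


@dataclass
class SelectionTrace:
    """Greedy selection path: chosen index names with cumulative metrics."""

    steps: list[tuple[str, EvalResult]]
    C: float
    sigma: float

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.steps]

    @property
    def best(self) -> tuple[str, EvalResult]:
        """First step achieving the maximum cumulative accuracy."""
        return max(self.steps, key=lambda s: s[1].accuracy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "index_name": self.names,
                "sensitivity": [r.sensitivity for _, r in self.steps],
                "specificity": [r.specificity for _, r in self.steps],
                "accuracy": [r.accuracy for _, r in self.steps],
            }
        )


def _greedy_steps(X, y, names, C, sigma, max_indices, splits, positive):
    """Greedy forward search given a standardized matrix; returns step list."""
    D_feat = _pairwise_sqdist_per_feature(X)
    name_to_col = {name: j for j, name in enumerate(names)}
    two_sig2 = 2.0 * sigma**2
    D_cur = np.zeros((y.size, y.size))
    remaining = sorted(names)
    steps: list[tuple[str, EvalResult]] = []
    for _ in range(min(max_indices, len(names))):
        best = None
        for cand in remaining:  # lexicographic order fixes tie-breaking
            D = D_cur + D_feat[name_to_col[cand]]
            preds = _svm_cv_predict_precomputed(np.exp(-D / two_sig2), y, C, splits)
            acc = float(np.mean(preds == y))
            if best is None or acc > best[1]:
                best = (cand, acc, preds)
        name, _, preds = best
        steps.append((name, evaluate(y, preds, positive)))
        D_cur = D_cur + D_feat[name_to_col[name]]
        remaining.remove(name)
    return steps


def greedy_svm_selection(features: pd.DataFrame, config: ClassifierConfig) -> SelectionTrace:
    """Forward greedy index selection at fixed ``(C, sigma)``.

    At each step the index maximizing cross-validated accuracy of the SVM on
    the enlarged set is added (ties to the lexicographically smallest name);
    cumulative sensitivity/specificity/accuracy are recorded per step.
    """
    if config.C is None or config.sigma is None:
        raise ValueError("greedy selection needs preset C and sigma (run grid search first)")
    X, y, names = _feature_matrix(features)
    if not names:
        raise ValueError("no candidate indices in feature table")
    if config.standardize:
        X, _ = _standardize_train_apply(X, X[:0])
    splits = cv_splits(y, config.cv, config.seed)
    steps = _greedy_steps(
        X, y, names, config.C, config.sigma, config.max_indices, splits, config.positive
    )
    return SelectionTrace(steps=steps, C=config.C, sigma=config.sigma)


def nested_greedy_svm_eval(
    features: pd.DataFrame, config: ClassifierConfig, inner_cv=("stratified", 3)
) -> EvalResult:
    """Unbiased variant of method D: greedy selection inside each training fold.

    Within each outer training fold, indices are chosen greedily by inner-CV
    accuracy; the prefix with the best inner accuracy is used to classify the
    held-out subjects.
    """
    if config.C is None or config.sigma is None:
        raise ValueError("nested evaluation needs preset C and sigma")
    X, y, names = _feature_matrix(features)
    preds = np.empty(y.size, dtype=y.dtype)
    for tr, te in cv_splits(y, config.cv, config.seed):
        Xtr, Xte = X[tr], X[te]
        if config.standardize:
            Xtr, Xte = _standardize_train_apply(Xtr, Xte)
        inner_splits = cv_splits(y[tr], inner_cv, config.seed)
        steps = _greedy_steps(
            Xtr, y[tr], names, config.C, config.sigma, config.max_indices,
            inner_splits, config.positive,
        )
        accs = [r.accuracy for _, r in steps]
        k = int(np.argmax(accs)) + 1
        chosen = [names.index(name) for name, _ in steps[:k]]
        clf = SVC(C=config.C, gamma=sigma_to_gamma(config.sigma), kernel="rbf")
        clf.fit(Xtr[:, chosen], y[tr])
        preds[te] = clf.predict(Xte[:, chosen])
    return evaluate(y, preds, config.positive)
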