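"""Model fitting, repeated cross-validation and model comparison.

The classifier is ridge-penalized logistic regression (fixed C = 1.0) on
within-fold z-scored features; with roughly 300 patients and up to 503
features regularization is required for a stable fit.  Around it sit, all
fitted strictly inside training folds to avoid leakage:

* a skewness-gated natural-log transform (columns with sample skewness > 0.5
  and strictly positive training values);
* optional SMOTE oversampling of the minority class (synthetic rows are
  convex combinations of a minority row and one of its k = 5 minority-class
  nearest neighbors), balancing classes 1:1;
* optional feature reduction: PCA or factor analysis retaining the
  components that explain 95% of training variance, recursive feature
  elimination (random-forest, linear-SVM or logistic-regression ranked,
  10% eliminated per step down to 10 features), or univariate ANOVA keeping
  the top 10 percentile.

Performance is the mean AUC over 5 stratified folds x 50 repeats (CV-AUC);
paired models are compared fold-wise with the DeLong test and the median of
the fold p values is reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FactorAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, SelectPercentile, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .selection import FeatureTable, ModelSpec

__all__ = [
    "SkewnessLogTransformer", "log_transform_skewed", "fit_reducer",
    "oversample_smote", "run_repeated_cv", "delong_test", "compare_models",
    "feature_importance", "CvResult", "ComparisonResult", "ImportanceResult",
]


# ---------------------------------------------------------------------------
# preprocessing


class SkewnessLogTransformer(BaseEstimator, TransformerMixin):
    """Natural-log transform of right-skewed, strictly positive columns.

    A column is transformed when its training-sample skewness exceeds
    ``skew_threshold`` and all its training values are > 0.  The decision is
    made at fit time only, so the transformer is safe inside CV folds.
    """

    def __init__(self, skew_threshold: float = 0.5):
        self.skew_threshold = skew_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        with np.errstate(invalid="ignore"):
            skew = stats.skew(X, axis=0, bias=True)
        positive = (X > 0).all(axis=0)
        self.transform_mask_ = (np.nan_to_num(skew) > self.skew_threshold) & positive
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        m = self.transform_mask_
        # unseen rows may contain non-positive values in a transformed column;
        # clip to a tiny positive number rather than produce -inf
        X[:, m] = np.log(np.clip(X[:, m], 1e-12, None))
        return X


def log_transform_skewed(table: FeatureTable,
                         skew_threshold: float = 0.5) -> FeatureTable:
    """Whole-table convenience wrapper (CV uses the transformer per fold)."""
    tr = SkewnessLogTransformer(skew_threshold).fit(table.X.values)
    X = pd.DataFrame(tr.transform(table.X.values), columns=table.X.columns)
    return FeatureTable(table.patient_ids, X, table.y, table.approach_id)


class _ConstantDropper(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.keep_ = X.std(axis=0) > 0
        if not self.keep_.all():
            warnings.warn(f"dropping {int((~self.keep_).sum())} constant feature(s) "
                          "before reduction")
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.keep_]


def _make_reducer(method: str, seed: int, n_features: int,
                  rfe_n_estimators: int = 500, rfe_target: int = 10):
    target = min(rfe_target, n_features)
    if method == "none":
        return None
    if method == "pca":
        return PCA(n_components=0.95, svd_solver="full", random_state=seed)
    if method == "fa":
        return _FactorAnalysisReducer(random_state=seed)
    if method == "rfe_rf":
        return RFE(RandomForestClassifier(n_estimators=rfe_n_estimators,
                                          random_state=seed, n_jobs=1),
                   n_features_to_select=target, step=0.1)
    if method == "rfe_svm":
        return RFE(LinearSVC(dual="auto", max_iter=5000, random_state=seed),
                   n_features_to_select=target, step=0.1)
    if method == "rfe_lr":
        return RFE(LogisticRegression(max_iter=2000, random_state=seed),
                   n_features_to_select=target, step=0.1)
    if method == "anova_top10pct":
        return SelectPercentile(f_classif, percentile=10)
    raise ValueError(f"unknown reduction method {method!r}")


class _FactorAnalysisReducer(BaseEstimator, TransformerMixin):
    """Factor analysis with the component count PCA needs for 95% variance."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y=None):
        k = PCA(n_components=0.95, svd_solver="full").fit(X).n_components_
        self.fa_ = FactorAnalysis(n_components=int(k), random_state=self.random_state)
        self.fa_.fit(X)
        return self

    def transform(self, X):
        return self.fa_.transform(X)


def fit_reducer(method: str, train_X: np.ndarray, train_y: np.ndarray,
                seed: int = 0, **kwargs):
    """Fit a feature-reduction transformer on training data only.

    Constant features are dropped (with a warning) before the reducer is
    fitted; the returned object transforms unseen rows consistently.
    """
    train_X = np.asarray(train_X, dtype=float)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training outcome must contain both classes")
    dropper = _ConstantDropper().fit(train_X)
    Xd = dropper.transform(train_X)
    reducer = _make_reducer(method, seed, Xd.shape[1], **kwargs)
    if reducer is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer.fit(Xd, train_y)

    class _Fitted:
        def __init__(self, dropper, reducer):
            self.dropper, self.reducer = dropper, reducer

        def transform(self, X):
            Xd = self.dropper.transform(X)
            return Xd if self.reducer is None else self.reducer.transform(Xd)

    return _Fitted(dropper, reducer)


# ---------------------------------------------------------------------------
# SMOTE


def oversample_smote(train_X: np.ndarray, train_y: np.ndarray,
                     k_neighbors: int = 5, seed: int | np.random.Generator = 0):
    """Balance classes 1:1 with SMOTE-interpolated synthetic minority rows.

    Each synthetic sample lies on the segment between a random minority row
    and one of its k minority-class nearest neighbors (k reduced when the
    minority class is smaller than k + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE needs both classes in the training data")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y
    Xm = X[y == minority]
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # first neighbor is the point itself
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    gamma = rng.uniform(0.0, 1.0, size=n_new)
    neigh = idx[base, pick]
    X_new = Xm[base] + gamma[:, None] * (Xm[neigh] - Xm[base])
    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# repeated stratified CV


@dataclass
class FoldPrediction:
    repeat: int
    fold: int
    test_index: np.ndarray
    scores: np.ndarray


@dataclass
class CvResult:
    spec: ModelSpec
    aucs: np.ndarray  # (n_repeats, n_folds)
    seed: int
    predictions: list[FoldPrediction] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.aucs))

    @property
    def sd_auc(self) -> float:
        """SD over all fold AUCs (the single +/- SD reported with a CV-AUC)."""
        return float(np.nanstd(self.aucs))


def _repeat_seed(master: int, repeat: int) -> int:
    seq = np.random.SeedSequence(entropy=master, spawn_key=(repeat,))
    return int(seq.generate_state(1)[0] % (2**31 - 1))


def _fit_and_score(X_tr, y_tr, X_te, spec: ModelSpec, seed: int,
                   rfe_n_estimators: int = 500):
    pipe_seed = seed
    logt = SkewnessLogTransformer().fit(X_tr)
    X_tr = logt.transform(X_tr)
    X_te = logt.transform(X_te)
    scaler = StandardScaler().fit(X_tr)
    X_tr = scaler.transform(X_tr)
    X_te = scaler.transform(X_te)
    y_fit = y_tr
    if spec.oversampling == "interpolate":
        X_tr, y_fit = oversample_smote(X_tr, y_tr, seed=np.random.default_rng(pipe_seed))
    reducer = fit_reducer(spec.reduction, X_tr, y_fit, seed=pipe_seed,
                          rfe_n_estimators=rfe_n_estimators)
    X_tr = reducer.transform(X_tr)
    X_te = reducer.transform(X_te)
    clf = LogisticRegression(penalty="l2", C=1.0, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_tr, y_fit)
    return clf.predict_proba(X_te)[:, 1]


def run_repeated_cv(table: FeatureTable, spec: ModelSpec, n_folds: int = 5,
                    n_repeats: int = 50, seed: int = 0,
                    keep_predictions: bool = False,
                    rfe_n_estimators: int = 500,
                    test_row_mutator=None) -> CvResult:
    """Outcome-stratified k-fold CV repeated ``n_repeats`` times.

    Every preprocessing step (log transform, scaling, SMOTE, reduction) is
    fitted on the 80% training split of each fold and applied to the unseen
    20%; the fold AUC is computed from the held-out scores.  Deterministic
    for a fixed master seed.

    ``test_row_mutator(X_test, test_indices) -> X_test`` is a leakage
    diagnostic: it rewrites held-out rows after the split, so a feature made
    outcome-correlated in test rows only must leave the CV-AUC unchanged in
    a leak-free pipeline.
    """
    if not table.has_both_classes():
        raise ValueError("outcome must contain both classes")
    X = table.X.values
    y = table.y
    aucs = np.full((n_repeats, n_folds), np.nan)
    preds: list[FoldPrediction] = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=_repeat_seed(seed, r))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[te])) < 2:  # cannot occur under stratification
                warnings.warn(f"fold {r}/{f} has a single class; skipped")
                continue
            X_te = X[te] if test_row_mutator is None else test_row_mutator(X[te].copy(), te)
            scores = _fit_and_score(X[tr], y[tr], X_te, spec,
                                    seed=_repeat_seed(seed, r * n_folds + f + 10_000),
                                    rfe_n_estimators=rfe_n_estimators)
            aucs[r, f] = roc_auc_score(y[te], scores)
            if keep_predictions:
                preds.append(FoldPrediction(r, f, te, scores))
    return CvResult(spec=spec, aucs=aucs, seed=seed, predictions=preds)


# ---------------------------------------------------------------------------
# DeLong test


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_components(scores: np.ndarray, y: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    r_all = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return auc, v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray):
    """Two-sided DeLong test for paired correlated AUCs.

    Returns ``(p, auc_a, auc_b)``.  Identical score vectors give p = 1.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    auc_a, v10_a, v01_a = _auc_components(scores_a, y)
    auc_b, v10_b, v01_b = _auc_components(scores_b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return p, float(auc_a), float(auc_b)


@dataclass
class ComparisonResult:
    spec_a: ModelSpec
    spec_b: ModelSpec
    fold_p_values: np.ndarray
    mean_auc_a: float
    mean_auc_b: float

    @property
    def median_p(self) -> float:
        return float(np.median(self.fold_p_values))


def compare_models(table_a: FeatureTable, spec_a: ModelSpec,
                   table_b: FeatureTable, spec_b: ModelSpec,
                   n_folds: int = 5, n_repeats: int = 50, seed: int = 0,
                   rfe_n_estimators: int = 500) -> ComparisonResult:
    """Fold-wise paired DeLong comparison with a shared fold layout.

    Both models are trained and scored on identical stratified folds (same
    patients, same splits), the DeLong p is computed per test fold, and the
    median p over all repeats x folds is the final p value.
    """
    if table_a.patient_ids != table_b.patient_ids or not np.array_equal(table_a.y, table_b.y):
        raise ValueError("tables must cover the same patients and outcomes")
    y = table_a.y
    Xa, Xb = table_a.X.values, table_b.X.values
    ps, aucs_a, aucs_b = [], [], []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=_repeat_seed(seed, r))
        for f, (tr, te) in enumerate(skf.split(Xa, y)):
            if len(np.unique(y[te])) < 2:  # fewer events than folds
                continue
            fold_seed = _repeat_seed(seed, r * n_folds + f + 10_000)
            sa = _fit_and_score(Xa[tr], y[tr], Xa[te], spec_a, fold_seed,
                                rfe_n_estimators)
            sb = _fit_and_score(Xb[tr], y[tr], Xb[te], spec_b, fold_seed,
                                rfe_n_estimators)
            p, auc_a, auc_b = delong_test(sa, sb, y[te])
            ps.append(p)
            aucs_a.append(auc_a)
            aucs_b.append(auc_b)
    return ComparisonResult(spec_a, spec_b, np.asarray(ps),
                            float(np.mean(aucs_a)), float(np.mean(aucs_b)))


# ---------------------------------------------------------------------------
# feature importance


@dataclass
class ImportanceResult:
    feature_names: list[str]
    importances: np.ndarray
    reduction: str

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.importances)[::-1][:k]
        return [(self.feature_names[i], float(self.importances[i])) for i in order]


def feature_importance(table: FeatureTable, spec: ModelSpec, seed: int = 0,
                       n_estimators: int = 500,
                       rfe_n_estimators: int = 500) -> ImportanceResult:
    """Relative random-forest importances of the features surviving the
    spec's reduction method; importances are non-negative and sum to one.

    PCA is rejected: its components are not interpretable features.
    """
    if spec.reduction == "pca":
        raise ValueError("PCA components are not interpretable features; "
                         "use a selecting reduction method or 'none'")
    X = table.X.values
    y = table.y
    logt = SkewnessLogTransformer().fit(X)
    Xs = StandardScaler().fit_transform(logt.transform(X))
    reducer = fit_reducer(spec.reduction, Xs, y, seed=seed,
                          rfe_n_estimators=rfe_n_estimators)
    Xr = reducer.transform(Xs)
    cols = np.asarray(table.X.columns)[reducer.dropper.keep_]
    inner = reducer.reducer
    if inner is None:
        names = list(cols)
    elif hasattr(inner, "get_support"):
        names = list(cols[inner.get_support()])
    else:  # factor analysis: importance attaches to latent factors
        names = [f"factor_{k + 1}" for k in range(Xr.shape[1])]
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1).fit(Xr, y)
    imp = rf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full(len(imp), 1.0 / len(imp))
    return ImportanceResult(names, imp, spec.reduction)
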