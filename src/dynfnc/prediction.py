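"""Individualized treatment-response prediction.

Leave-one-out cross-validated epsilon-SVR (linear kernel) predicts each
subject's cognitive change score from baseline connectivity features.
Inside every fold, features are ranked by the absolute Pearson correlation
with the target computed on the *training* subjects only (kept if p <
alpha, uncorrected), and models with the top 1..m features are fit; feature
standardization also uses training-fold statistics only, so the held-out
subject never influences its own fold.  The reported accuracy is the
Pearson correlation R(m) between observed and pooled predicted change
scores, maximized over m; consensus features are those selected in every
fold at the best m.  Because best-m selection looks at the pooled
predictions, R(best) is optimistic — ``permutation_pvalue`` quantifies the
optimism by re-running the whole procedure on permuted targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .errors import ArgumentError, DegenerateDataError, EmptySelectionError


@dataclass
class PredictionResult:
    """LOOCV outcome: R(m) curve, best m, per-fold selections, consensus."""

    feature_names: list[str]
    observed: np.ndarray
    r_curve: dict[int, float]
    best_m: int
    r_best: float
    predicted: np.ndarray  # at best m; NaN where the fold selected nothing
    fold_rankings: list[list[str]] = field(default_factory=list)
    consensus: list[str] = field(default_factory=list)
    permutation_p: float | None = None

    @property
    def n_subjects(self) -> int:
        return self.observed.size

    def to_json_dict(self) -> dict:
        return {
            "r_curve": {str(m): v for m, v in sorted(self.r_curve.items())},
            "best_m": self.best_m,
            "r_best": self.r_best,
            "observed": self.observed.tolist(),
            "predicted": self.predicted.tolist(),
            "fold_rankings": self.fold_rankings,
            "consensus": self.consensus,
            "permutation_p": self.permutation_p,
        }


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r of X with y, plus two-sided p (t distribution)."""
    n = y.size
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sx > 0) & (sy > 0), xc.T @ yc / (sx * sy), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(r) < 1.0, r * np.sqrt((n - 2) / (1.0 - r**2)), np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def rank_features(
    train_features: np.ndarray | pd.DataFrame,
    train_target: np.ndarray,
    alpha: float = 0.05,
) -> list[int]:
    """Correlation-ranked feature selection on training data.

    Keeps features whose Pearson correlation with the target has p < alpha
    (uncorrected) and orders them by |r| descending; ties break toward the
    lower feature index.  Returns column indices (possibly empty).
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=float)
    if X.shape[0] != y.size:
        raise ArgumentError("feature rows and target length differ")
    if y.size < 3:
        raise ArgumentError("need at least 3 training subjects")
    r, p = _pearson_with_p(X, y)
    passing = np.flatnonzero(p < alpha)
    return sorted(passing.tolist(), key=lambda i: (-abs(r[i]), i))


def _fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    C: float,
    epsilon: float,
) -> float:
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    model = SVR(kernel="linear", C=C, epsilon=epsilon)
    model.fit((X_train - mu) / sd, y_train)
    return float(model.predict(((x_test - mu) / sd).reshape(1, -1))[0])


def loocv_svr(
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    max_features: int | None = None,
    alpha: float = 0.05,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> PredictionResult:
    """Leave-one-out SVR with per-fold incremental feature selection.

    For every held-out subject, features are re-ranked on the remaining
    n - 1 subjects and linear-kernel SVR models with the top 1..m features
    are fit (training-fold standardization).  ``max_features`` defaults to
    the smallest fold's passing-feature count, capped at n - 2.  A fold in
    which no feature passes alpha contributes no prediction; if every fold
    is empty the run aborts.
    """
    if features.columns.duplicated().any():
        raise ArgumentError("feature names must be unique")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ArgumentError("features contain missing values")
    y = np.asarray(target, dtype=float)
    n, _ = X.shape
    if y.size != n:
        raise ArgumentError("target length must match the number of subjects")
    if n < 4:
        raise ArgumentError("need at least 4 subjects for leave-one-out prediction")
    if y.std() == 0:
        raise DegenerateDataError("target is constant")
    names = [str(c) for c in features.columns]

    fold_rank_idx: list[list[int]] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[:] = True
        mask[i] = False
        fold_rank_idx.append(rank_features(X[mask], y[mask], alpha=alpha))
    nonempty = [len(r) for r in fold_rank_idx if r]
    if not nonempty:
        raise EmptySelectionError("no feature passed alpha in any leave-one-out fold")
    if max_features is None:
        max_features = min(nonempty)
    max_features = max(1, min(max_features, n - 2))

    preds = np.full((max_features, n), np.nan)
    for i in range(n):
        ranked = fold_rank_idx[i]
        if not ranked:
            continue
        mask[:] = True
        mask[i] = False
        for m in range(1, max_features + 1):
            cols = ranked[: min(m, len(ranked))]
            preds[m - 1, i] = _fit_predict(X[mask][:, cols], y[mask], X[i, cols], C, epsilon)

    r_curve: dict[int, float] = {}
    for m in range(1, max_features + 1):
        ok = ~np.isnan(preds[m - 1])
        if ok.sum() >= 3 and preds[m - 1, ok].std() > 0 and y[ok].std() > 0:
            r_curve[m] = float(np.corrcoef(y[ok], preds[m - 1, ok])[0, 1])
        else:
            r_curve[m] = float("nan")
    finite = {m: v for m, v in r_curve.items() if np.isfinite(v)}
    if not finite:
        raise EmptySelectionError("no feature count yielded a defined prediction correlation")
    best_m = max(finite, key=lambda m: (finite[m], -m))
    result = PredictionResult(
        feature_names=names,
        observed=y.copy(),
        r_curve=r_curve,
        best_m=best_m,
        r_best=finite[best_m],
        predicted=preds[best_m - 1].copy(),
        fold_rankings=[[names[i] for i in ranked] for ranked in fold_rank_idx],
    )
    result.consensus = consensus_features(result)
    return result


def consensus_features(result: PredictionResult) -> list[str]:
    """Features selected by *every* fold at the best feature count.

    The intersection over folds of each fold's top-(best m) list; folds
    that selected nothing make the consensus empty.  Order follows the
    feature matrix; an empty list is a valid outcome, not an error.
    """
    if not result.fold_rankings:
        raise ArgumentError("result contains no folds")
    m = result.best_m
    common: set[str] | None = None
    for ranked in result.fold_rankings:
        top = set(ranked[: min(m, len(ranked))])
        common = top if common is None else (common & top)
    assert common is not None
    return [name for name in result.feature_names if name in common]


def permutation_pvalue(
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    n_perm: int = 99,
    seed: int = 0,
    **loocv_kwargs,
) -> tuple[float, PredictionResult]:
    """Permutation significance of R(best).

    The full LOOCV procedure (per-fold re-ranking included) is re-run on
    ``n_perm`` random permutations of the target;
    p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).  Permutations where no
    fold selects any feature count as no evidence of signal.
    """
    if n_perm < 99:
        raise ArgumentError("n_perm must be >= 99 for a meaningful permutation p")
    result = loocv_svr(features, target, **loocv_kwargs)
    rng = np.random.default_rng(seed)
    y = np.asarray(target, dtype=float)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            r_perm = loocv_svr(features, y_perm, **loocv_kwargs).r_best
        except EmptySelectionError:
            continue
        if r_perm >= result.r_best:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    result.permutation_p = p
    return p, result
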