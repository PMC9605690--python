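"""Cross-validated ridge regression core.

Implements the explained-variance machinery every encoding analysis relies
on: fivefold outer cross-validation on contiguous temporal blocks within
trials, a ridge penalty whose strength is chosen by nested fivefold
cross-validation on the training folds, the coefficient of determination

    R^2 = 1 - SSE / SST,

negative cross-validated values clipped to zero after fold averaging, and
unique explained variance (UEV): the drop in cross-validated R^2 when a
subset of regressors is temporally shuffled within trials,

    UEV = R^2_intact - R^2_shuffled.

Folds are contiguous blocks (not random frames) because both fluorescence
and behavior are strongly autocorrelated; random frame-level folds would
leak training information into the test sets.

All fits run on sufficient statistics (per-block Gram matrices and cross
moments), so a full nested cross-validation costs a handful of passes over
the data regardless of the fold counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CVConfig",
    "CVResult",
    "BlockRidge",
    "blocked_folds",
    "r_squared",
    "cross_validated_r2",
    "unique_explained_variance",
    "shuffle_within_trials",
]

DEFAULT_ALPHAS = tuple(float(a) for a in np.logspace(-3, 3, 7))


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings shared by all regression analyses."""

    k_outer: int = 5
    k_inner: int = 5
    alphas: tuple = DEFAULT_ALPHAS
    n_shuffles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be >= 2")
        if any(a <= 0 for a in self.alphas):
            raise ValueError("ridge alphas must be positive")


@dataclass
class CVResult:
    """Outcome of one cross-validated regression."""

    r2: float  # fold-averaged R^2, clipped at 0
    fold_r2: np.ndarray  # raw per-fold values (may be negative)
    fold_alphas: np.ndarray  # length k_outer; NaN where a fold was skipped
    oof_prediction: np.ndarray | None = None

    @property
    def r2_raw(self) -> float:
        return float(np.mean(self.fold_r2))


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination; negative when SSE exceeds SST."""
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-12:
        raise ZeroDivisionError("R^2 undefined for a constant target (SST = 0)")
    sse = float(np.sum((y - np.asarray(y_hat, dtype=float)) ** 2))
    return 1.0 - sse / sst


def pd_unique(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


def blocked_folds(trial_ids: np.ndarray, k: int) -> list[np.ndarray]:
    """k folds of contiguous blocks, built within each trial.

    Rows are assumed time-ordered within each trial.  Every trial
    contributes one contiguous block to every fold, so each fold spans all
    trials while respecting temporal contiguity.
    """
    trial_ids = np.asarray(trial_ids)
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for trial in pd_unique(trial_ids):
        idx = np.flatnonzero(trial_ids == trial)
        if idx.size < k:
            raise ValueError(f"trial {trial!r} has fewer rows than folds")
        for f, block in enumerate(np.array_split(idx, k)):
            folds[f].append(block)
    return [np.concatenate(b) for b in folds]


class _Moments:
    """Sufficient statistics of (X, y) over a row subset."""

    __slots__ = ("G", "s", "q", "ysum", "yy", "n")

    def __init__(self, G, s, q, ysum, yy, n):
        self.G, self.s, self.q = G, s, q
        self.ysum, self.yy, self.n = ysum, yy, n

    @classmethod
    def of(cls, X: np.ndarray, y: np.ndarray, idx: np.ndarray) -> "_Moments":
        Xb = X[idx]
        yb = y[idx]
        return cls(Xb.T @ Xb, Xb.sum(axis=0), Xb.T @ yb, yb.sum(), float(yb @ yb), idx.size)

    def __add__(self, other: "_Moments") -> "_Moments":
        return _Moments(
            self.G + other.G,
            self.s + other.s,
            self.q + other.q,
            self.ysum + other.ysum,
            self.yy + other.yy,
            self.n + other.n,
        )

    def __sub__(self, other: "_Moments") -> "_Moments":
        return _Moments(
            self.G - other.G,
            self.s - other.s,
            self.q - other.q,
            self.ysum - other.ysum,
            self.yy - other.yy,
            self.n - other.n,
        )

    @property
    def sst(self) -> float:
        return self.yy - self.ysum**2 / self.n


def _ridge_fits(train: _Moments, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ridge solutions for every alpha from training moments.

    Regressors are standardized to the training mean/std (the penalty acts
    on the standardized scale); returns coefficients on the original scale
    (p, n_alphas) and intercepts (n_alphas,).
    """
    n = train.n
    mu = train.s / n
    ymean = train.ysum / n
    var = np.diag(train.G) / n - mu**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd = np.where(sd < 1e-12, 1.0, sd)
    Gc = (train.G - np.outer(train.s, train.s) / n) / np.outer(sd, sd)
    bc = (train.q - mu * train.ysum) / sd
    p = mu.size
    coefs = np.empty((p, alphas.size))
    eye = np.eye(p)
    for i, a in enumerate(alphas):
        try:
            ws = np.linalg.solve(Gc + a * eye, bc)
        except np.linalg.LinAlgError:
            ws = np.linalg.lstsq(Gc + a * eye, bc, rcond=None)[0]
        coefs[:, i] = ws / sd
    intercepts = ymean - mu @ coefs
    return coefs, intercepts


def _fold_r2(test: _Moments, coefs: np.ndarray, intercepts: np.ndarray) -> np.ndarray:
    """Held-out R^2 per alpha, from test-block moments alone."""
    sst = test.sst
    quad = np.einsum("pa,pq,qa->a", coefs, test.G, coefs)
    sse = (
        test.yy
        - 2.0 * coefs.T @ test.q
        - 2.0 * intercepts * test.ysum
        + quad
        + 2.0 * intercepts * (coefs.T @ test.s)
        + test.n * intercepts**2
    )
    return 1.0 - sse / sst


def _inner_select_alpha(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    trial_ids: np.ndarray,
    alphas: np.ndarray,
    k_inner: int,
) -> tuple[float, _Moments]:
    """Pick the penalty by blocked CV inside the training rows.

    Returns the selected alpha and the training-set moments (reused for the
    final fit).  Ties break toward the smaller alpha.
    """
    local_trials = trial_ids[train_idx]
    blocks = [train_idx[b] for b in blocked_folds(local_trials, k_inner)]
    mom = [_Moments.of(X, y, b) for b in blocks]
    total = mom[0]
    for m in mom[1:]:
        total = total + m
    if alphas.size == 1:
        return float(alphas[0]), total
    scores = np.zeros(alphas.size)
    counts = 0
    for m in mom:
        if m.sst < 1e-12:
            continue
        coefs, icepts = _ridge_fits(total - m, alphas)
        scores += _fold_r2(m, coefs, icepts)
        counts += 1
    if counts == 0:
        return float(alphas[alphas.size // 2]), total
    return float(alphas[int(np.argmax(np.round(scores / counts, 12)))]), total


class BlockRidge(BaseEstimator, RegressorMixin):
    """Ridge regression with blocked inner-CV penalty selection.

    Regressors are standardized on the training data and the intercept is
    the training mean; the ridge coefficient is chosen from ``alphas`` by
    k-fold cross-validation on contiguous blocks within trials, maximizing
    mean held-out R^2.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients on the original (unstandardized) scale.
    intercept_ : float
    alpha_ : float
        Selected penalty.
    """

    def __init__(self, alphas: tuple = DEFAULT_ALPHAS, k_inner: int = 5):
        self.alphas = alphas
        self.k_inner = k_inner

    def fit(self, X, y, trial_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per target sample")
        if trial_ids is None:
            trial_ids = np.zeros(X.shape[0], dtype=int)
        alphas = np.asarray(self.alphas, dtype=float)
        idx = np.arange(X.shape[0])
        self.alpha_, total = _inner_select_alpha(X, y, idx, np.asarray(trial_ids), alphas, self.k_inner)
        coefs, icepts = _ridge_fits(total, np.array([self.alpha_]))
        self.coef_ = coefs[:, 0]
        self.intercept_ = float(icepts[0])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _as_design(X: np.ndarray, n_rows: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X[:, None]
    if X.shape[0] != n_rows and X.shape[1] == n_rows:
        return X.T
    return X


def cross_validated_r2(
    X: np.ndarray,
    y: np.ndarray,
    trial_ids: np.ndarray | None = None,
    cv: CVConfig = CVConfig(),
    fold_alphas: np.ndarray | None = None,
    keep_oof: bool = False,
) -> CVResult:
    """Fold-averaged cross-validated ridge R^2.

    Per outer fold the penalty is chosen by inner blocked CV on the
    training data (or taken from ``fold_alphas`` when given, e.g. when
    re-scoring shuffled designs); R^2 is evaluated on the held-out block.
    Raw per-fold values are retained; the summary ``r2`` is the fold mean
    clipped below at zero.  Folds whose test block has a constant target
    are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X, y.size)
    if trial_ids is None:
        trial_ids = np.zeros(y.size, dtype=int)
    trial_ids = np.asarray(trial_ids)
    if np.sum((y - y.mean()) ** 2) < 1e-12:
        raise ZeroDivisionError("R^2 undefined for a constant target (SST = 0)")
    folds = blocked_folds(trial_ids, cv.k_outer)
    all_idx = np.arange(y.size)
    alphas = np.asarray(cv.alphas, dtype=float)
    mid_alpha = float(alphas[alphas.size // 2])
    fold_r2: list[float] = []
    alphas_used = np.full(cv.k_outer, np.nan)
    oof = np.full(y.size, np.nan) if keep_oof else None
    fold_moms = None
    if fold_alphas is not None:
        # re-scoring with fixed per-fold penalties: one moment pass suffices
        fold_moms = [_Moments.of(X, y, test) for test in folds]
        grand = fold_moms[0]
        for m in fold_moms[1:]:
            grand = grand + m
    for f, test in enumerate(folds):
        test_mom = fold_moms[f] if fold_moms is not None else _Moments.of(X, y, test)
        if test_mom.sst < 1e-12:
            warnings.warn(f"fold {f}: constant test target; fold skipped", RuntimeWarning)
            continue
        if fold_alphas is not None:
            a = float(fold_alphas[f])
            alpha = a if np.isfinite(a) else mid_alpha
            total = grand - test_mom
        else:
            train = np.setdiff1d(all_idx, test)
            alpha, total = _inner_select_alpha(X, y, train, trial_ids, alphas, cv.k_inner)
        coefs, icepts = _ridge_fits(total, np.array([alpha]))
        fold_r2.append(float(_fold_r2(test_mom, coefs, icepts)[0]))
        alphas_used[f] = alpha
        if keep_oof:
            oof[test] = X[test] @ coefs[:, 0] + icepts[0]
    if not fold_r2:
        raise ValueError("no valid folds (all test blocks had constant targets)")
    fold_arr = np.asarray(fold_r2)
    return CVResult(
        r2=float(max(fold_arr.mean(), 0.0)),
        fold_r2=fold_arr,
        fold_alphas=alphas_used,
        oof_prediction=oof,
    )


def shuffle_within_trials(
    values: np.ndarray, trial_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Jointly permute rows of ``values`` in time, independently per trial."""
    out = values.copy()
    for trial in pd_unique(trial_ids):
        idx = np.flatnonzero(trial_ids == trial)
        out[idx] = values[idx[rng.permutation(idx.size)]]
    return out


def unique_explained_variance(
    X: np.ndarray,
    y: np.ndarray,
    group_cols,
    trial_ids: np.ndarray | None = None,
    cv: CVConfig = CVConfig(),
    intact: CVResult | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, CVResult]:
    """UEV of a regressor subset by within-trial temporal shuffling.

    The subset's rows are jointly permuted in time within each trial
    (``cv.n_shuffles`` seeded permutations, averaged); the shuffled designs
    are re-scored with the per-fold penalties of the intact fit.  Both the
    intact and the mean shuffled R^2 are clipped at zero before
    differencing, and the UEV itself is clipped below at zero.
    """
    group_cols = np.asarray(group_cols, dtype=int)
    if group_cols.size == 0:
        raise ValueError("empty regressor group")
    y = np.asarray(y, dtype=float)
    X = _as_design(X, y.size)
    if trial_ids is None:
        trial_ids = np.zeros(X.shape[0], dtype=int)
    trial_ids = np.asarray(trial_ids)
    if rng is None:
        rng = np.random.default_rng(cv.seed)
    if intact is None:
        intact = cross_validated_r2(X, y, trial_ids, cv)
    shuffled_means = []
    for _ in range(cv.n_shuffles):
        Xs = X.copy()
        Xs[:, group_cols] = shuffle_within_trials(X[:, group_cols], trial_ids, rng)
        res = cross_validated_r2(Xs, y, trial_ids, cv, fold_alphas=intact.fold_alphas)
        shuffled_means.append(res.fold_r2.mean())
    r2_shuffled = max(float(np.mean(shuffled_means)), 0.0)
    return max(intact.r2 - r2_shuffled, 0.0), intact


# ---------------------------------------------------------------------------
# Batched variants: many independent models scored in one pass.
# ---------------------------------------------------------------------------


@dataclass
class BatchCVResult:
    """Per-model results of a batched cross-validated regression."""

    r2: np.ndarray  # (m,) clipped fold means
    fold_r2: np.ndarray  # (k_outer, m) raw; NaN where a fold was skipped
    fold_alphas: np.ndarray  # (k_outer, m)

    @property
    def r2_raw(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.fold_r2, axis=0)


def _clipped_mean(fold_r2: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(fold_r2, axis=0)
    return np.clip(m, 0.0, None)


class _BatchMomentsMulti:
    """Moments of shared X against many targets Y over a row block."""

    __slots__ = ("G", "s", "Q", "ysum", "yy", "n")

    def __init__(self, X, Y, idx):
        Xb = X[idx]
        Yb = Y[idx]
        self.G = Xb.T @ Xb
        self.s = Xb.sum(axis=0)
        self.Q = Xb.T @ Yb
        self.ysum = Yb.sum(axis=0)
        self.yy = np.einsum("ij,ij->j", Yb, Yb)
        self.n = idx.size

    @staticmethod
    def total(moms):
        out = object.__new__(_BatchMomentsMulti)
        out.G = sum(m.G for m in moms)
        out.s = sum(m.s for m in moms)
        out.Q = sum(m.Q for m in moms)
        out.ysum = sum(m.ysum for m in moms)
        out.yy = sum(m.yy for m in moms)
        out.n = sum(m.n for m in moms)
        return out

    def select(self, cols):
        out = object.__new__(_BatchMomentsMulti)
        out.G, out.s, out.n = self.G, self.s, self.n
        out.Q = self.Q[:, cols]
        out.ysum = self.ysum[cols]
        out.yy = self.yy[cols]
        return out

    def minus(self, other):
        out = object.__new__(_BatchMomentsMulti)
        out.G = self.G - other.G
        out.s = self.s - other.s
        out.Q = self.Q - other.Q
        out.ysum = self.ysum - other.ysum
        out.yy = self.yy - other.yy
        out.n = self.n - other.n
        return out

    @property
    def sst(self):
        return self.yy - self.ysum**2 / self.n


def _multi_fits(train: "_BatchMomentsMulti", alphas: np.ndarray):
    """Ridge coefficients (n_alpha, p, m) and intercepts (n_alpha, m)."""
    n = train.n
    mu = train.s / n
    ymean = train.ysum / n
    var = np.diag(train.G) / n - mu**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd = np.where(sd < 1e-12, 1.0, sd)
    Gc = (train.G - np.outer(train.s, train.s) / n) / np.outer(sd, sd)
    Bc = (train.Q - np.outer(train.s, train.ysum) / n) / sd[:, None]
    p = mu.size
    coefs = np.empty((alphas.size, p, Bc.shape[1]))
    eye = np.eye(p)
    for i, a in enumerate(alphas):
        try:
            W = np.linalg.solve(Gc + a * eye, Bc)
        except np.linalg.LinAlgError:
            W = np.linalg.lstsq(Gc + a * eye, Bc, rcond=None)[0]
        coefs[i] = W / sd[:, None]
    icepts = ymean[None, :] - np.einsum("p,apm->am", mu, coefs)
    return coefs, icepts


def _multi_r2(test: "_BatchMomentsMulti", coefs: np.ndarray, icepts: np.ndarray):
    """(n_alpha, m) held-out R^2 from test moments."""
    sst = test.sst
    quad = np.einsum("apm,pq,aqm->am", coefs, test.G, coefs)
    lin = np.einsum("apm,pm->am", coefs, test.Q)
    slin = np.einsum("apm,p->am", coefs, test.s)
    sse = (
        test.yy[None, :]
        - 2.0 * lin
        - 2.0 * icepts * test.ysum[None, :]
        + quad
        + 2.0 * icepts * slin
        + test.n * icepts**2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - sse / sst[None, :]


def batch_cv_r2_multi(
    X: np.ndarray,
    Y: np.ndarray,
    trial_ids: np.ndarray | None = None,
    cv: CVConfig = CVConfig(),
    fold_alphas: np.ndarray | None = None,
) -> BatchCVResult:
    """Nested-CV ridge R^2 of one design against many targets at once.

    Equivalent to calling :func:`cross_validated_r2` per column of ``Y``
    (same folds, same alpha grid, per-target alpha selection), but sharing
    the Gram computations across targets.  ``fold_alphas`` (k_outer, m)
    skips alpha selection, for re-scoring shuffled designs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    m = Y.shape[1]
    if trial_ids is None:
        trial_ids = np.zeros(Y.shape[0], dtype=int)
    trial_ids = np.asarray(trial_ids)
    folds = blocked_folds(trial_ids, cv.k_outer)
    alphas = np.asarray(cv.alphas, dtype=float)
    mid_alpha = float(alphas[alphas.size // 2])
    all_idx = np.arange(Y.shape[0])
    fold_r2 = np.full((cv.k_outer, m), np.nan)
    used = np.full((cv.k_outer, m), np.nan)
    test_moms = [_BatchMomentsMulti(X, Y, test) for test in folds]
    for f, test in enumerate(folds):
        test_mom = test_moms[f]
        valid = test_mom.sst > 1e-12
        if not valid.any():
            continue
        train = np.setdiff1d(all_idx, test)
        if fold_alphas is None:
            # inner alpha selection, per target
            inner_blocks = [train[b] for b in blocked_folds(trial_ids[train], cv.k_inner)]
            inner_moms = [_BatchMomentsMulti(X, Y, b) for b in inner_blocks]
            total = _BatchMomentsMulti.total(inner_moms)
            scores = np.zeros((alphas.size, m))
            counts = np.zeros(m)
            for mm in inner_moms:
                v = mm.sst > 1e-12
                if not v.any():
                    continue
                coefs, icepts = _multi_fits(total.minus(mm), alphas)
                r2 = _multi_r2(mm, coefs, icepts)
                scores[:, v] += r2[:, v]
                counts[v] += 1.0
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_scores = scores / counts[None, :]
            best = np.where(
                counts > 0,
                np.argmax(np.round(mean_scores, 12), axis=0),
                alphas.size // 2,
            )
            alpha_f = alphas[best]
        else:
            alpha_f = np.where(np.isfinite(fold_alphas[f]), fold_alphas[f], mid_alpha)
            total = None
        if total is None:
            total = _BatchMomentsMulti.total(test_moms).minus(test_mom)
        # final fit per distinct alpha, evaluate on the outer test block
        for a in np.unique(alpha_f):
            cols = np.flatnonzero((alpha_f == a) & valid)
            if cols.size == 0:
                continue
            coefs, icepts = _multi_fits(total.select(cols), np.array([a]))
            fold_r2[f, cols] = _multi_r2(test_mom.select(cols), coefs, icepts)[0]
            used[f, cols] = a
    return BatchCVResult(r2=_clipped_mean(fold_r2), fold_r2=fold_r2, fold_alphas=used)


class _BatchMomentsSingle:
    """Per-column moments for many independent single-regressor models
    sharing one target y."""

    __slots__ = ("sx", "sxx", "sxy", "ysum", "yy", "n")

    def __init__(self, X, y, idx):
        Xb = X[idx]
        yb = y[idx]
        self.sx = Xb.sum(axis=0)
        self.sxx = np.einsum("ij,ij->j", Xb, Xb)
        self.sxy = yb @ Xb
        self.ysum = yb.sum()
        self.yy = float(yb @ yb)
        self.n = idx.size

    def minus(self, other):
        out = object.__new__(_BatchMomentsSingle)
        out.sx = self.sx - other.sx
        out.sxx = self.sxx - other.sxx
        out.sxy = self.sxy - other.sxy
        out.ysum = self.ysum - other.ysum
        out.yy = self.yy - other.yy
        out.n = self.n - other.n
        return out

    @staticmethod
    def total(moms):
        out = object.__new__(_BatchMomentsSingle)
        out.sx = sum(m.sx for m in moms)
        out.sxx = sum(m.sxx for m in moms)
        out.sxy = sum(m.sxy for m in moms)
        out.ysum = sum(m.ysum for m in moms)
        out.yy = sum(m.yy for m in moms)
        out.n = sum(m.n for m in moms)
        return out

    @property
    def sst(self):
        return self.yy - self.ysum**2 / self.n


def _single_fits(train: "_BatchMomentsSingle", alphas: np.ndarray):
    """Closed-form per-column ridge: coefs and intercepts (n_alpha, m)."""
    n = train.n
    mu = train.sx / n
    ymean = train.ysum / n
    var = train.sxx / n - mu**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd = np.where(sd < 1e-12, 1.0, sd)
    gc = n * np.clip(var, 0.0, None) / sd**2  # = n for non-degenerate cols
    bc = (train.sxy - mu * train.ysum) / sd
    ws = bc[None, :] / (gc[None, :] + alphas[:, None])
    coefs = ws / sd[None, :]
    icepts = ymean - mu[None, :] * coefs
    return coefs, icepts


def _single_r2(test: "_BatchMomentsSingle", coefs, icepts):
    sst = test.sst
    sse = (
        test.yy
        - 2.0 * coefs * test.sxy[None, :]
        - 2.0 * icepts * test.ysum
        + coefs**2 * test.sxx[None, :]
        + 2.0 * icepts * coefs * test.sx[None, :]
        + test.n * icepts**2
    )
    return 1.0 - sse / sst


def batch_cv_r2_single(
    X: np.ndarray,
    y: np.ndarray,
    trial_ids: np.ndarray | None = None,
    cv: CVConfig = CVConfig(),
    fold_alphas: np.ndarray | None = None,
) -> BatchCVResult:
    """Nested-CV ridge R^2 of many single-regressor models at once.

    Each column of ``X`` is an independent one-regressor model of the shared
    target ``y`` (the behavior-encoding-map geometry).  Same folds and alpha
    grid as :func:`cross_validated_r2`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = X.shape[1]
    if trial_ids is None:
        trial_ids = np.zeros(y.size, dtype=int)
    trial_ids = np.asarray(trial_ids)
    if np.sum((y - y.mean()) ** 2) < 1e-12:
        raise ZeroDivisionError("R^2 undefined for a constant target (SST = 0)")
    folds = blocked_folds(trial_ids, cv.k_outer)
    alphas = np.asarray(cv.alphas, dtype=float)
    mid_alpha = float(alphas[alphas.size // 2])
    all_idx = np.arange(y.size)
    fold_r2 = np.full((cv.k_outer, m), np.nan)
    used = np.full((cv.k_outer, m), np.nan)
    test_moms = [_BatchMomentsSingle(X, y, t) for t in folds]
    grand = _BatchMomentsSingle.total(test_moms)
    for f, test in enumerate(folds):
        test_mom = test_moms[f]
        if test_mom.sst < 1e-12:
            continue
        if fold_alphas is None:
            train = np.setdiff1d(all_idx, test)
            inner_blocks = [train[b] for b in blocked_folds(trial_ids[train], cv.k_inner)]
            inner_moms = [_BatchMomentsSingle(X, y, b) for b in inner_blocks]
            total = _BatchMomentsSingle.total(inner_moms)
            scores = np.zeros((alphas.size, m))
            counts = 0
            for mm in inner_moms:
                if mm.sst < 1e-12:
                    continue
                coefs, icepts = _single_fits(total.minus(mm), alphas)
                scores += _single_r2(mm, coefs, icepts)
                counts += 1
            if counts == 0:
                alpha_f = np.full(m, mid_alpha)
            else:
                alpha_f = alphas[np.argmax(np.round(scores / counts, 12), axis=0)]
        else:
            alpha_f = np.where(np.isfinite(fold_alphas[f]), fold_alphas[f], mid_alpha)
            total = grand.minus(test_mom)
        # evaluate each column with its own alpha (vectorized over alphas)
        coefs_all, icepts_all = _single_fits(total, alphas)
        col_alpha_idx = np.searchsorted(alphas, alpha_f)
        col_alpha_idx = np.clip(col_alpha_idx, 0, alphas.size - 1)
        # columns whose alpha is not on the grid (fixed external): solve direct
        on_grid = np.isclose(alphas[col_alpha_idx], alpha_f)
        r2_all = _single_r2(test_mom, coefs_all, icepts_all)
        rows = np.arange(m)
        fold_r2[f] = r2_all[col_alpha_idx, rows]
        if not on_grid.all():
            off = np.flatnonzero(~on_grid)
            for a in np.unique(alpha_f[off]):
                cols = off[alpha_f[off] == a]
                coefs, icepts = _single_fits(total, np.array([a]))
                fold_r2[f, cols] = _single_r2(test_mom, coefs, icepts)[0][cols]
        used[f] = alpha_f
    return BatchCVResult(r2=_clipped_mean(fold_r2), fold_r2=fold_r2, fold_alphas=used)


def batch_uev_single(
    X: np.ndarray,
    y: np.ndarray,
    trial_ids: np.ndarray | None = None,
    cv: CVConfig = CVConfig(),
    intact: BatchCVResult | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, BatchCVResult]:
    """Per-column UEV for single-regressor models (shuffle the regressor).

    One within-trial permutation per shuffle round, applied to every column
    (models are independent, so sharing the permutation is valid).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if trial_ids is None:
        trial_ids = np.zeros(y.size, dtype=int)
    trial_ids = np.asarray(trial_ids)
    if rng is None:
        rng = np.random.default_rng(cv.seed)
    if intact is None:
        intact = batch_cv_r2_single(X, y, trial_ids, cv)
    acc = np.zeros(X.shape[1])
    for _ in range(cv.n_shuffles):
        Xs = shuffle_within_trials(X, trial_ids, rng)
        res = batch_cv_r2_single(Xs, y, trial_ids, cv, fold_alphas=intact.fold_alphas)
        acc += res.r2_raw
    shuffled = np.clip(acc / cv.n_shuffles, 0.0, None)
    return np.clip(intact.r2 - shuffled, 0.0, None), intact


def batch_uev_multi(
    X: np.ndarray,
    Y: np.ndarray,
    group_cols,
    trial_ids: np.ndarray | None = None,
    cv: CVConfig = CVConfig(),
    intact: BatchCVResult | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, BatchCVResult]:
    """UEV of a regressor subset for many targets sharing one design."""
    group_cols = np.asarray(group_cols, dtype=int)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if trial_ids is None:
        trial_ids = np.zeros(Y.shape[0], dtype=int)
    trial_ids = np.asarray(trial_ids)
    if rng is None:
        rng = np.random.default_rng(cv.seed)
    if intact is None:
        intact = batch_cv_r2_multi(X, Y, trial_ids, cv)
    acc = np.zeros(Y.shape[1])
    for _ in range(cv.n_shuffles):
        Xs = X.copy()
        Xs[:, group_cols] = shuffle_within_trials(X[:, group_cols], trial_ids, rng)
        res = batch_cv_r2_multi(Xs, Y, trial_ids, cv, fold_alphas=intact.fold_alphas)
        acc += res.r2_raw
    shuffled = np.clip(acc / cv.n_shuffles, 0.0, None)
    return np.clip(intact.r2 - shuffled, 0.0, None), intact
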