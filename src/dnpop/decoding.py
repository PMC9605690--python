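"""Residual-based odor decoding.

Behavior-predictable activity is removed from each neuron's ΔF/F by
cross-validated ridge regression on crf-convolved behavior regressors
(predictions made on held-out folds only); linear-discriminant classifiers
then decode odor presence (ACV vs humid air, MSC vs humid air) from the
residuals at the frame level, and the scores are compared against
classifiers given only the behavior regressors, with a two-sided
Mann-Whitney U test across trial x fold score points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .encoding import FlySession
from .regression import CVConfig, batch_cv_r2_multi, blocked_folds, _BatchMomentsMulti, _multi_fits

__all__ = ["BehaviorResidualizer", "behavior_residuals", "residual_odor_classifier", "compare_feature_sets"]


class BehaviorResidualizer(BaseEstimator, TransformerMixin):
    """Remove behavior-predictable variance from neural traces.

    For each neuron, a ridge model on the crf-convolved behavior regressors
    is fit per cross-validation fold and its held-out prediction subtracted,
    so the residual at every frame comes from a model that never saw that
    frame.  The ridge penalty per fold is selected by nested blocked CV.

    Attributes
    ----------
    residuals_ : (n_neurons, n_frames)
    fold_r2_ : per-neuron raw fold R^2 of the behavior model
    """

    def __init__(self, cv: CVConfig = CVConfig()):
        self.cv = cv

    def fit(self, X_behavior, traces, trial_ids=None):
        X = np.asarray(X_behavior, dtype=float)
        Y = np.asarray(traces, dtype=float).T  # frames x neurons
        if trial_ids is None:
            trial_ids = np.zeros(X.shape[0], dtype=int)
        trial_ids = np.asarray(trial_ids)
        res = batch_cv_r2_multi(X, Y, trial_ids, self.cv)
        folds = blocked_folds(trial_ids, self.cv.k_outer)
        all_idx = np.arange(X.shape[0])
        pred = np.full(Y.shape, np.nan)
        fold_moms = [_BatchMomentsMulti(X, Y, t) for t in folds]
        grand = _BatchMomentsMulti.total(fold_moms)
        mid = self.cv.alphas[len(self.cv.alphas) // 2]
        for f, test in enumerate(folds):
            train_mom = grand.minus(fold_moms[f])
            alpha_f = res.fold_alphas[f]
            alpha_f = np.where(np.isfinite(alpha_f), alpha_f, mid)
            for a in np.unique(alpha_f):
                cols = np.flatnonzero(alpha_f == a)
                coefs, icepts = _multi_fits(train_mom.select(cols), np.array([a]))
                pred[np.ix_(test, cols)] = X[test] @ coefs[0] + icepts[0]
        self.residuals_ = (Y - pred).T
        self.fold_r2_ = res.fold_r2
        self.cv_r2_ = res.r2
        return self

    def transform(self, X=None):
        check_is_fitted(self, "residuals_")
        return self.residuals_


def behavior_residuals(session: FlySession, cv: CVConfig = CVConfig()) -> np.ndarray:
    """Neuron x frame residual matrix of a session (behavior model removed)."""
    d = session.design
    cols = d.columns(d.groups["behavior"])
    rz = BehaviorResidualizer(cv=cv)
    rz.fit(d.values[:, cols], session.traces, session.trial_ids)
    return rz.residuals_


def _balanced_lda_scores(
    features: np.ndarray,
    is_odor: np.ndarray,
    trial_ids: np.ndarray,
    cv: CVConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per (trial, fold) held-out accuracy of an LDA odor-vs-air decoder."""
    rows = []
    for trial in pd.unique(trial_ids):
        sel = np.flatnonzero(trial_ids == trial)
        folds = blocked_folds(np.zeros(sel.size, int), cv.k_outer)
        for f, test_loc in enumerate(folds):
            test = sel[test_loc]
            train = np.setdiff1d(sel, test)
            tr_pos = train[is_odor[train]]
            tr_neg = train[~is_odor[train]]
            te_pos = test[is_odor[test]]
            te_neg = test[~is_odor[test]]
            if min(tr_pos.size, tr_neg.size) < 5 or min(te_pos.size, te_neg.size) < 5:
                warnings.warn(f"trial {trial} fold {f}: a class is missing; fold skipped")
                continue
            # balance classes by subsampling the commoner one (seeded)
            n_tr = min(tr_pos.size, tr_neg.size)
            n_te = min(te_pos.size, te_neg.size)
            tr_idx = np.concatenate(
                [rng.choice(tr_pos, n_tr, replace=False), rng.choice(tr_neg, n_tr, replace=False)]
            )
            te_idx = np.concatenate(
                [rng.choice(te_pos, n_te, replace=False), rng.choice(te_neg, n_te, replace=False)]
            )
            n_feat = features.shape[1]
            shrink = tr_idx.size < 5 * n_feat
            clf = (
                LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                if shrink
                else LinearDiscriminantAnalysis()
            )
            clf.fit(features[tr_idx], is_odor[tr_idx])
            rows.append(
                {
                    "trial_id": trial,
                    "fold": f,
                    "score": float(clf.score(features[te_idx], is_odor[te_idx])),
                    "n_test": int(2 * n_te),
                }
            )
    return pd.DataFrame(rows)


def residual_odor_classifier(
    session: FlySession,
    odor: str,
    cv: CVConfig = CVConfig(),
    residuals: np.ndarray | None = None,
) -> pd.DataFrame:
    """Frame-level odor-vs-air decoding from residuals and from behavior.

    Returns per (feature set, trial, fold) held-out accuracies for the
    requested odor against humid air, with classes balanced by seeded
    subsampling.  Feature sets: ``residual`` (neural residuals) and
    ``behavior`` (the crf-convolved behavior regressors).
    """
    rng = np.random.default_rng(cv.seed)
    if residuals is None:
        residuals = behavior_residuals(session, cv)
    d = session.design
    beh = d.values[:, d.columns(d.groups["behavior"] + d.groups["rotation"])]
    odor_mask = session.odor_mask(odor)
    air_mask = session.odor_mask("air")
    use = odor_mask | air_mask
    is_odor = odor_mask[use]
    tid = session.trial_ids[use]
    frames = np.flatnonzero(use)
    out = []
    for name, feats in (("residual", residuals.T[frames]), ("behavior", beh[frames])):
        df = _balanced_lda_scores(feats, is_odor, tid, cv, np.random.default_rng(rng.integers(2**31)))
        df["feature_set"] = name
        df["odor"] = odor
        out.append(df)
    return pd.concat(out, ignore_index=True)


def compare_feature_sets(scores: pd.DataFrame) -> dict:
    """Two-sided Mann-Whitney U test: residual vs behavior score points."""
    res = scores.loc[scores.feature_set == "residual", "score"].to_numpy()
    beh = scores.loc[scores.feature_set == "behavior", "score"].to_numpy()
    if res.size < 2 or beh.size < 2:
        return {
            "n_points": int(min(res.size, beh.size)),
            "mean_residual": float(res.mean()) if res.size else np.nan,
            "mean_behavior": float(beh.mean()) if beh.size else np.nan,
            "U": np.nan,
            "p_value": np.nan,
        }
    stat = mannwhitneyu(res, beh, alternative="two-sided")
    return {
        "n_points": int(min(res.size, beh.size)),
        "mean_residual": float(res.mean()),
        "mean_behavior": float(beh.mean()),
        "U": float(stat.statistic),
        "p_value": float(stat.pvalue),
    }
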