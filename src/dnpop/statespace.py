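"""Population state-space analysis on TV-regularized ΔF/F derivatives.

PCA is fit on the per-neuron derivative time series restricted to walking
frames only; resting (or any other) epochs are embedded with the
walking-fit mean and components, without refitting.  High-loading ROIs are
selected by the criterion w_pc1^2 + w_pc2^2 > 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .signals import DerivativeConfig, tv_derivative

__all__ = ["WalkingPCA", "EmbeddedEpoch", "derivative_matrix", "label_epochs"]

LOADING_CUTOFF = 0.1


@dataclass
class EmbeddedEpoch:
    """One behavior epoch's trajectory in PC space."""

    behavior: str
    trial_id: object
    times: np.ndarray
    scores: np.ndarray  # frames x components


def derivative_matrix(
    traces: np.ndarray, dt: float, cfg: DerivativeConfig = DerivativeConfig()
) -> np.ndarray:
    """TV-regularized time derivative of each row of a trace matrix."""
    return np.vstack([tv_derivative(row, cfg, dt=dt) for row in np.atleast_2d(traces)])


def label_epochs(
    labels: np.ndarray, behavior: str, times: np.ndarray, min_duration: float = 1.0
) -> list[tuple[int, int]]:
    """Contiguous runs of one behavior label lasting at least min_duration."""
    idx = np.flatnonzero(labels == behavior)
    if idx.size == 0:
        return []
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    out = []
    for s in splits:
        if times[s[-1]] - times[s[0]] >= min_duration:
            out.append((int(s[0]), int(s[-1]) + 1))
    return out


class WalkingPCA(BaseEstimator, TransformerMixin):
    """PCA of neural-derivative state space, trained on walking frames.

    The input per trial is a neuron x frame %ΔF/F matrix; derivatives are
    computed per neuron per trial with total-variation regularization
    (lambda = 5000 by default), concatenated across trials, and PCA is fit
    on the walking-frame derivative vectors only (covariance PCA: neurons
    share ΔF/F units, so no variance scaling).

    Parameters
    ----------
    n_components : int or None
        Passed to :class:`sklearn.decomposition.PCA`.
    tv_lambda : float
        Regularization weight of the derivative estimator.
    loading_cutoff : float
        Threshold on w_pc1^2 + w_pc2^2 for selecting high-loading ROIs.

    Attributes
    ----------
    components_ : (n_components, n_neurons)
    explained_variance_ratio_ : (n_components,)
    mean_ : (n_neurons,) training mean of the derivative vectors
    derivatives_ : (n_neurons, n_frames) concatenated derivative matrix
    walking_mask_ : (n_frames,) frames the PCA was fit on
    """

    def __init__(
        self,
        n_components: int | None = None,
        tv_lambda: float = 5000.0,
        loading_cutoff: float = LOADING_CUTOFF,
    ):
        self.n_components = n_components
        self.tv_lambda = tv_lambda
        self.loading_cutoff = loading_cutoff

    def fit(self, trial_traces, trial_labels, dt: float):
        """Fit on a fly's trials.

        Parameters
        ----------
        trial_traces : list of (n_neurons, n_frames) arrays
        trial_labels : list of per-neural-frame behavior label arrays
        dt : float
            Neural frame period in seconds.
        """
        cfg = DerivativeConfig(tv_lambda=self.tv_lambda)
        derivs = [derivative_matrix(tr, dt, cfg) for tr in trial_traces]
        self.derivatives_ = np.hstack(derivs)
        self.trial_ids_ = np.concatenate(
            [np.full(d.shape[1], i) for i, d in enumerate(derivs)]
        )
        labels = np.concatenate(trial_labels)
        self.walking_mask_ = labels == "walking"
        n_neurons = self.derivatives_.shape[0]
        if n_neurons < 2:
            raise ValueError("need at least 2 neurons for a state space")
        if self.walking_mask_.sum() < 10 * n_neurons:
            raise ValueError("insufficient walking frames to fit the PCA")
        self._pca = PCA(n_components=self.n_components)
        self._pca.fit(self.derivatives_[:, self.walking_mask_].T)
        self.components_ = self._pca.components_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.mean_ = self._pca.mean_
        self.labels_ = labels
        return self

    def transform(self, X):
        """Project derivative vectors (frames x neurons) into PC space."""
        check_is_fitted(self, "components_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def embed_epochs(
        self, behavior: str, times: np.ndarray, min_duration: float = 1.0
    ) -> list[EmbeddedEpoch]:
        """Project epochs of a behavior with the walking-fit components."""
        check_is_fitted(self, "components_")
        epochs = label_epochs(self.labels_, behavior, times, min_duration)
        out = []
        for s, e in epochs:
            out.append(
                EmbeddedEpoch(
                    behavior=behavior,
                    trial_id=self.trial_ids_[s],
                    times=times[s:e],
                    scores=self.transform(self.derivatives_[:, s:e].T),
                )
            )
        return out

    def high_loading_rois(self) -> np.ndarray:
        """Indices of ROIs with w_pc1^2 + w_pc2^2 above the cutoff."""
        check_is_fitted(self, "components_")
        w = self.components_
        norm2 = w[0] ** 2 + (w[1] ** 2 if w.shape[0] > 1 else 0.0)
        return np.flatnonzero(norm2 > self.loading_cutoff)

    def loadings_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "components_")
        w = self.components_
        return pd.DataFrame(
            {
                "neuron_id": np.arange(w.shape[1]),
                "w_pc1": w[0],
                "w_pc2": w[1] if w.shape[0] > 1 else np.zeros(w.shape[1]),
                "selected": np.isin(np.arange(w.shape[1]), self.high_loading_rois()),
            }
        )
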