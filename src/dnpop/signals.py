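"""Signal-level primitives shared by all analysis stages.

This module houses the calcium response function (crf) kernel, causal
convolution of behavior regressors with the crf, the %ΔF/F baseline rule,
resampling between the 100 Hz behavior grid and the ~16 Hz two-photon frame
grid, and total-variation-regularized differentiation of fluorescence traces.

The crf is the double-exponential

    crf(t) = -exp(-a t) + exp(-b t),   a > b > 0,

normalized to integrate to one on [0, 30] s.  With the GCaMP6s constants
a = 7.4 /s (rise) and b = 0.3 /s (decay) it peaks at ~0.45 s and decays over
several seconds, which is why binary behavior indicators must be convolved
with it before being compared with fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.linalg import cholesky_banded, cho_solve_banded

__all__ = [
    "CRFKernel",
    "BaselineConfig",
    "DerivativeConfig",
    "TraceMatrix",
    "make_crf_kernel",
    "convolve_with_crf",
    "compute_dff",
    "resample_to_neural",
    "tv_derivative",
]

DEFAULT_CRF_A = 7.4
DEFAULT_CRF_B = 0.3


@dataclass(frozen=True)
class CRFKernel:
    """Sampled calcium response kernel on [0, t_max].

    Attributes
    ----------
    a, b : float
        Rise and decay rate constants (1/s), a > b > 0.
    dt : float
        Sample spacing in seconds.
    t_max : float
        Support length in seconds (default 30).
    samples : ndarray
        Kernel values on the grid ``arange(0, t_max + dt/2, dt)``, scaled so
        the trapezoidal integral over the support equals one.
    """

    a: float
    b: float
    dt: float
    t_max: float
    samples: np.ndarray = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the sliding-window fluorescence baseline."""

    window: int = 15
    near_zero_mask_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("baseline window must be >= 1 frame")


@dataclass(frozen=True)
class DerivativeConfig:
    """Parameters of the TV-regularized derivative estimator."""

    tv_lambda: float = 5000.0
    max_iter: int = 500
    tol: float = 1e-5  # relative duality-gap tolerance

    def __post_init__(self) -> None:
        if self.tv_lambda <= 0:
            raise ValueError("tv_lambda must be positive")


@dataclass
class TraceMatrix:
    """One trial's neuron x frame %ΔF/F matrix with its time base."""

    values: np.ndarray
    frame_times: np.ndarray
    neuron_ids: np.ndarray
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D neuron x frame matrix")
        if self.values.shape[1] != self.frame_times.size:
            raise ValueError("frame_times length must match the frame axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("one neuron_id per row required")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def make_crf_kernel(
    a: float = DEFAULT_CRF_A,
    b: float = DEFAULT_CRF_B,
    dt: float = 0.01,
    t_max: float = 30.0,
) -> CRFKernel:
    """Build the normalized calcium response kernel.

    Parameters
    ----------
    a, b : float
        Rise and decay rate constants (1/s); requires ``a > b > 0`` for a
        unimodal nonnegative kernel.
    dt : float
        Sample spacing (s); use the behavior frame period when the kernel is
        convolved with 100 Hz regressors.
    t_max : float
        Support length (s).  The normalization integrates over [0, t_max].
    """
    if not (a > b > 0):
        raise ValueError("crf requires a > b > 0 (rise faster than decay)")
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    t = np.arange(0.0, t_max + dt / 2, dt)
    raw = -np.exp(-a * t) + np.exp(-b * t)
    area = np.trapezoid(raw, dx=dt)
    return CRFKernel(a=a, b=b, dt=dt, t_max=t_max, samples=raw / area)


def convolve_with_crf(series: np.ndarray, kernel: CRFKernel) -> np.ndarray:
    """Causally convolve a per-frame series with the crf.

    The output at frame ``k`` is ``sum_j series[k - j] * kernel[j] * dt``;
    output length equals input length, so the result depends only on past
    and present input.  2-D inputs are convolved row-wise.
    """
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    rows = np.atleast_2d(series)
    n = rows.shape[1]
    out = _sig.fftconvolve(rows, kernel.samples[None, :], axes=1)[:, :n]
    out *= kernel.dt
    return out[0] if one_d else out


def _sliding_window_min_mean(trace: np.ndarray, window: int, eps: float) -> float:
    """Minimum length-`window` sliding mean, ignoring windows touching
    near-zero frames (motion-correction padding artifacts)."""
    n = trace.size
    if n < window:
        raise ValueError("trace shorter than the baseline window")
    means = np.convolve(trace, np.ones(window) / window, mode="valid")
    bad = trace < eps
    if bad.any():
        bad_window = np.convolve(bad.astype(float), np.ones(window), mode="valid") > 0
        means = means[~bad_window]
        if means.size == 0:
            return np.inf
    return float(means.min())


def compute_dff(
    raw_trials: list[np.ndarray],
    cfg: BaselineConfig = BaselineConfig(),
) -> list[np.ndarray]:
    """Convert raw fluorescence to %ΔF/F with a cross-trial baseline.

    Per neuron, the baseline F0 is the minimum over *all* trials of the
    minimum sliding-window (length ``cfg.window``, stride 1) mean of the raw
    trace; %ΔF/F = 100 (F - F0) / F0.  Frames below
    ``cfg.near_zero_mask_eps`` are excluded from baseline candidate windows.
    """
    if not raw_trials:
        raise ValueError("at least one trial required")
    mats = [np.asarray(t, dtype=float) for t in raw_trials]
    n_neurons = mats[0].shape[0]
    if any(m.shape[0] != n_neurons for m in mats):
        raise ValueError("inconsistent neuron count across trials")
    f0 = np.empty(n_neurons)
    for i in range(n_neurons):
        f0[i] = min(
            _sliding_window_min_mean(m[i], cfg.window, cfg.near_zero_mask_eps)
            for m in mats
        )
    if np.any(~np.isfinite(f0)) or np.any(f0 <= 0):
        bad = np.where(~np.isfinite(f0) | (f0 <= 0))[0]
        raise ValueError(f"invalid (non-positive) baseline for neurons {bad.tolist()}")
    return [100.0 * (m - f0[:, None]) / f0[:, None] for m in mats]


def resample_to_neural(
    series: np.ndarray,
    behavior_times: np.ndarray,
    neural_times: np.ndarray,
) -> np.ndarray:
    """Linearly interpolate a behavior-rate series at neural frame times."""
    behavior_times = np.asarray(behavior_times, dtype=float)
    neural_times = np.asarray(neural_times, dtype=float)
    span = 1e-9 + (behavior_times[-1] - behavior_times[0])
    if neural_times[0] < behavior_times[0] - 1e-3 * span or neural_times[-1] > behavior_times[-1] + 1e-3 * span:
        raise ValueError("neural frame times fall outside the behavior time span")
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        return np.interp(neural_times, behavior_times, series)
    return np.vstack([np.interp(neural_times, behavior_times, row) for row in series])


def _apply_D(c: np.ndarray, dt: float) -> np.ndarray:
    # rows i = 0..n-2: (c[i+1] - 2 c[i] + c[i-1]) / dt with c[-1] := 0
    out = np.empty(c.size - 1)
    out[0] = (c[1] - 2.0 * c[0]) / dt
    out[1:] = (c[2:] - 2.0 * c[1:-1] + c[:-2]) / dt
    return out


def _apply_Dt(z: np.ndarray, dt: float) -> np.ndarray:
    n = z.size + 1
    out = np.zeros(n)
    out[0] -= 2.0 * z[0]
    out[1] += z[0]
    if z.size > 1:
        zi = z[1:]
        out[: n - 2] += zi
        out[1 : n - 1] -= 2.0 * zi
        out[2:n] += zi
    return out / dt


def tv_derivative(
    trace: np.ndarray,
    cfg: DerivativeConfig = DerivativeConfig(),
    dt: float = 1.0,
) -> np.ndarray:
    """Total-variation-regularized derivative of a 1-D trace.

    Solves ``min_u ||A u - (trace - trace[0])||^2 + lambda * TV(u)`` where
    ``A`` is the running-sum (antiderivative) operator with step ``dt`` and
    ``TV(u) = sum_i |u[i+1] - u[i]|``.  Substituting the antiderivative
    ``c = A u`` turns this into an L1 trend-filtering problem in ``c`` with a
    second-difference penalty, solved exactly by ADMM with a banded Cholesky
    factorization (O(n) per iteration).  The estimate is deterministic for a
    fixed config.

    Returns the derivative estimate ``u`` (same length as the input, units of
    trace units per second when ``dt`` is in seconds).
    """
    b = np.asarray(trace, dtype=float)
    if b.ndim != 1 or b.size < 3:
        raise ValueError("trace must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(b)):
        raise ValueError("trace must be finite")
    b = b - b[0]
    n = b.size
    # The objective equals 2 * ( 0.5 ||c-b||^2 + (lam/2) ||D c||_1 ) in the
    # antiderivative variable c, i.e. L1 trend filtering with weight lam/2.
    lam = cfg.tv_lambda / 2.0
    m = n - 1  # number of penalty rows

    # Dual problem: min_nu 0.5 nu' H nu - nu' D b  s.t. |nu_i| <= lam, with
    # c = b - D' nu.  H = D D' is pentadiagonal: [1, -4, 6, -4, 1] / dt^2
    # (5 instead of 6 at the first diagonal entry, implicit c[-1] = 0 row).
    inv2 = 1.0 / dt**2
    h_main = np.full(m, 6.0 * inv2)
    h_main[0] = 5.0 * inv2
    h_off1 = np.full(m - 1, -4.0 * inv2)
    h_off2 = np.full(max(m - 2, 0), inv2)
    q = _apply_D(b, dt)

    def h_mv(v: np.ndarray) -> np.ndarray:
        out = h_main * v
        out[:-1] += h_off1 * v[1:]
        out[1:] += h_off1 * v[:-1]
        if m > 2:
            out[:-2] += h_off2 * v[2:]
            out[2:] += h_off2 * v[:-2]
        return out

    # Primal-dual interior-point iteration on the box-constrained dual QP
    # (one Newton step per iteration, banded Cholesky solves, O(n) each).
    nu = np.zeros(m)
    mu1 = np.ones(m)
    mu2 = np.ones(m)
    t_ip = 0.0
    scale = max(1.0, float(b @ b))
    converged = False
    gap = np.inf
    for _ in range(cfg.max_iter):
        hnu = h_mv(nu)
        dt_nu = _apply_Dt(nu, dt)
        # surrogate duality gap between the primal trend-filter objective and
        # the dual QP objective
        pobj = 0.5 * float(dt_nu @ dt_nu) + lam * float(np.abs(q - hnu).sum())
        dobj = -0.5 * float(dt_nu @ dt_nu) + float(q @ nu)
        gap = pobj - dobj
        if gap <= cfg.tol * scale:
            converged = True
            break
        t_ip = max(2.0 * m * 2.0 / gap, 1.2 * t_ip)
        f1 = nu - lam  # < 0
        f2 = -nu - lam  # < 0
        diag_extra = -(mu1 / f1 + mu2 / f2)  # positive
        rhs = -(hnu - q) + (1.0 / t_ip) / f1 - (1.0 / t_ip) / f2
        ab = np.zeros((3, m))
        ab[0, 2:] = h_off2
        ab[1, 1:] = h_off1
        ab[2, :] = h_main + diag_extra
        dnu = cho_solve_banded((cholesky_banded(ab), False), rhs)
        dmu1 = -(mu1 + ((1.0 / t_ip) + dnu * mu1) / f1)
        dmu2 = -(mu2 + ((1.0 / t_ip) - dnu * mu2) / f2)
        # largest step keeping mu > 0 and |nu| < lam
        s = 1.0
        neg1 = dmu1 < 0
        neg2 = dmu2 < 0
        if neg1.any():
            s = min(s, 0.99 * float((-mu1[neg1] / dmu1[neg1]).min()))
        if neg2.any():
            s = min(s, 0.99 * float((-mu2[neg2] / dmu2[neg2]).min()))
        for _ls in range(40):
            cand = nu + s * dnu
            if np.all(np.abs(cand) < lam):
                break
            s *= 0.5
        # backtracking on the norm of the primal-dual residual
        def residual(nu_, mu1_, mu2_):
            f1_ = nu_ - lam
            f2_ = -nu_ - lam
            r_dual = h_mv(nu_) - q + mu1_ - mu2_
            r_cent = np.concatenate([-mu1_ * f1_ - 1.0 / t_ip, -mu2_ * f2_ - 1.0 / t_ip])
            return np.concatenate([r_dual, r_cent])

        res0 = np.linalg.norm(residual(nu, mu1, mu2))
        for _ls in range(40):
            if (
                np.linalg.norm(residual(nu + s * dnu, mu1 + s * dmu1, mu2 + s * dmu2))
                <= (1.0 - 0.01 * s) * res0
            ):
                break
            s *= 0.5
        nu = nu + s * dnu
        mu1 = mu1 + s * dmu1
        mu2 = mu2 + s * dmu2
    if not converged and cfg.tol > 0:
        import warnings

        warnings.warn(
            f"tv_derivative: interior-point solver stopped at duality gap "
            f"{gap:.2e} after {cfg.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    c = b - _apply_Dt(nu, dt)
    u = np.empty(n)
    u[0] = c[0] / dt
    u[1:] = np.diff(c) / dt
    return u
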