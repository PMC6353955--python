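"""FRAP trace normalization, single-exponential recovery fitting and
derived mobility measures.

A FRAP experiment records three circular ROIs over time: the bleached spot
(ROI1), a non-bleached control in the same compartment (ROI2, reports
acquisition bleaching) and a background ROI next to the cell.  After
background subtraction (primed quantities), the double normalization

    I(t) = (mean_pre(ROI2') / ROI2'(t)) * (ROI1'(t) / mean_pre(ROI1'))

sets the pre-bleach level to 1 and cancels any multiplicative intensity
drift common to both ROIs (e.g. acquisition photobleaching).  The recovery
of the normalized post-bleach signal is fitted with

    I_fit(t) = I0 - a * exp(-beta * t)

from which the half-time of recovery t_1/2 = ln(2)/beta and the immobile
fraction Imof = 1 - a / (1 - (I0 - a)) follow.  Imof is the proportion of
molecules that do not exchange during the observation window: the fit's
starting level is I0 - a, so 1 - (I0 - a) is the bleached depth and the
recovered amplitude a is compared with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FRAPTrace:
    """Raw three-ROI FRAP recording.

    All series share the time axis ``t`` (seconds, strictly increasing);
    the first ``n_pre`` frames are pre-bleach.
    """

    t: np.ndarray
    i_roi1: np.ndarray
    i_roi2: np.ndarray
    i_bg: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_roi1 = np.asarray(self.i_roi1, dtype=float)
        self.i_roi2 = np.asarray(self.i_roi2, dtype=float)
        self.i_bg = np.asarray(self.i_bg, dtype=float)
        n = self.t.size
        if not (self.i_roi1.size == self.i_roi2.size == self.i_bg.size == n):
            raise ValueError("all series must have the same length")
        if n < self.n_pre + 2:
            raise ValueError("trace too short for its pre-bleach frame count")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")


@dataclass
class FRAPFit:
    """Fitted single-exponential recovery and derived quantities."""

    i0: float
    a: float
    beta: float
    t_half: float
    imof: float
    rss: float


def normalize_trace(trace: FRAPTrace) -> np.ndarray:
    """Double-normalized intensity series (pre-bleach level ~= 1)."""
    roi1 = trace.i_roi1 - trace.i_bg
    roi2 = trace.i_roi2 - trace.i_bg
    pre = slice(0, trace.n_pre)
    m1 = roi1[pre].mean()
    m2 = roi2[pre].mean()
    if m1 == 0 or m2 == 0:
        raise ValueError("zero pre-bleach mean in a background-subtracted ROI")
    if np.any(roi2 == 0):
        raise ValueError("zero background-subtracted control ROI value")
    return (m2 / roi2) * (roi1 / m1)


def _model(t: np.ndarray, i0: float, a: float, beta: float) -> np.ndarray:
    return i0 - a * np.exp(-beta * t)


def fit_recovery(intensity: np.ndarray, t: np.ndarray, n_pre: int) -> FRAPFit:
    """Least-squares fit of ``I0 - a*exp(-beta*t)`` to the post-bleach frames.

    Time is rebased to zero at the first post-bleach frame.  The fit is
    restarted from five deterministic initializations (beta from a
    log-linear regression of ``log(I0_hat - I)`` plus a geometric grid
    spanning the recording length); the best residual sum of squares wins.
    """
    intensity = np.asarray(intensity, dtype=float)
    t = np.asarray(t, dtype=float)
    i_post = intensity[n_pre:]
    t_post = t[n_pre:] - t[n_pre]
    if i_post.size < 5:
        raise ValueError("need at least 5 post-bleach frames")
    if np.ptp(i_post) < 1e-12:
        raise ValueError("no recovery signal: flat post-bleach trace")

    i0_hat = float(i_post[max(i_post.size - max(3, i_post.size // 10), 0):].mean())
    a_hat = max(float(i0_hat - i_post[0]), 1e-6)

    betas = []
    resid = i0_hat + 1e-3 - i_post
    ok = resid > 0
    if ok.sum() >= 3:
        slope = np.polyfit(t_post[ok], np.log(resid[ok]), 1)[0]
        if slope < 0:
            betas.append(-slope)
    t_span = t_post[-1] if t_post[-1] > 0 else 1.0
    betas.extend(np.log(2) / (t_span * np.array([0.02, 0.1, 0.3, 1.0])))
    betas = betas[:5]

    best = None
    for b0 in betas:
        try:
            popt, _ = curve_fit(
                _model,
                t_post,
                i_post,
                p0=[i0_hat, a_hat, b0],
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum(((_model(t_post, *popt)) - i_post) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("recovery fit did not converge from any initialization")
    (i0, a, beta), rss = best
    return FRAPFit(
        i0=float(i0),
        a=float(a),
        beta=float(beta),
        t_half=half_time(beta),
        imof=immobile_fraction(i0, a),
        rss=rss,
    )


def immobile_fraction(i0: float, a: float) -> float:
    """Imof = 1 - a / (1 - (I0 - a)); requires a post-bleach floor below 1."""
    denom = 1.0 - (i0 - a)
    if denom <= 0:
        raise ValueError("post-bleach floor at or above pre-bleach level")
    return 1.0 - a / denom


def half_time(beta: float) -> float:
    """Half-time of recovery t_1/2 = ln(2)/beta (seconds)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(np.log(2) / beta)


def fit_trace(trace: FRAPTrace) -> FRAPFit:
    """Normalize a raw trace and fit the recovery model (per-cell pipeline)."""
    return fit_recovery(normalize_trace(trace), trace.t, trace.n_pre)


def bootstrap_ci(
    intensity: np.ndarray,
    t: np.ndarray,
    n_pre: int,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap percentile confidence intervals for (I0, a, beta).

    Residuals of the best fit are resampled with replacement onto the
    fitted curve and the model refitted ``n_boot`` times.
    """
    rng = np.random.default_rng(seed)
    fit = fit_recovery(intensity, t, n_pre)
    intensity = np.asarray(intensity, dtype=float)
    t = np.asarray(t, dtype=float)
    t_post = t[n_pre:] - t[n_pre]
    fitted = _model(t_post, fit.i0, fit.a, fit.beta)
    resid = intensity[n_pre:] - fitted
    samples = {"i0": [], "a": [], "beta": []}
    for _ in range(n_boot):
        synth = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            bf = fit_recovery(
                np.concatenate([intensity[:n_pre], synth]), t, n_pre
            )
        except (ValueError, RuntimeError):
            continue
        samples["i0"].append(bf.i0)
        samples["a"].append(bf.a)
        samples["beta"].append(bf.beta)
    alpha = (1.0 - level) / 2.0
    return {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
        for k, v in samples.items()
        if len(v) > 0
    }
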