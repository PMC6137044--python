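"""FRAP recovery analysis.

Normalizes fluorescence-recovery-after-photobleaching traces to the
pre-bleach plateau, fits a single-exponential recovery

    F(t) = F0 + (Finf - F0) * (1 - exp(-ln2 * t / t_half)),

and converts the recovery halftime to a lateral diffusion coefficient via
the uniform-circular-beam relation D = gamma * w^2 / (4 * t_half).

The model is parameterized directly in ``t_half`` so the headline quantity
is a fit parameter rather than a derived one.  The mobile fraction is
(Finf - F0) / (Fpre - F0) with Fpre fixed at 1 after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

LN2 = np.log(2.0)


@dataclass
class FrapTrace:
    """A FRAP intensity time series.

    ``time_s`` is zero at the first post-bleach sample; the ``n_pre``
    pre-bleach samples carry negative times.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    n_pre: int
    roi_radius_um: float = 0.5

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time_s and intensity must have equal length")
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.roi_radius_um <= 0:
            raise ValueError("roi_radius_um must be positive")

    @property
    def post_mask(self) -> np.ndarray:
        return self.time_s >= 0

    @property
    def n_post(self) -> int:
        return int(np.count_nonzero(self.post_mask))


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters."""

    f_pre: float
    f0: float
    f_inf: float
    t_half_s: float
    mobile_fraction: float
    residual_norm: float
    d_um2_s: float | None = None
    flat_model_warning: bool = False


class FitNonConvergence(RuntimeError):
    """Raised when the optimizer fails; carries the best iterate seen."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


def recovery_model(t, f0, gain, t_half):
    """Exponential recovery with plateau gain = Finf - F0."""
    return f0 + gain * (1.0 - np.exp(-LN2 * t / t_half))


def normalize_trace(raw: FrapTrace) -> FrapTrace:
    """Divide intensities by the mean of the pre-bleach samples.

    After normalization the pre-bleach mean is exactly 1.
    """
    pre = raw.intensity[: raw.n_pre]
    mean = float(np.mean(pre))
    if mean <= 0:
        raise ValueError(f"pre-bleach mean must be positive, got {mean}")
    return replace(raw, intensity=raw.intensity / mean)


class ExponentialRecovery(BaseEstimator):
    """Single-exponential FRAP recovery fit (sklearn-style estimator).

    Fit on post-bleach samples of a *normalized* trace (pre-bleach plateau
    at 1).  ``gamma`` and the bleach-spot radius enter only the conversion
    of the fitted halftime to a diffusion coefficient and are kept explicit
    because the literature value of the geometry factor varies with the
    bleach profile.

    Parameters
    ----------
    gamma : float
        Geometry factor of the halftime-to-D relation (0.88 for a uniform
        circular beam).
    roi_radius_um : float or None
        Bleach-spot radius w in micrometers; if given, ``d_um2_s_`` is
        computed as gamma * w^2 / (4 * t_half).

    Attributes
    ----------
    f0_, f_inf_, t_half_s_, mobile_fraction_, residual_norm_ : float
    d_um2_s_ : float or None
    flat_model_warning_ : bool
        True when a flat (no-recovery) model beats the exponential by AIC.
    """

    def __init__(self, gamma: float = 0.88, roi_radius_um: float | None = None):
        self.gamma = gamma
        self.roi_radius_um = roi_radius_um

    def fit(self, X, y):
        """Fit the recovery curve.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Post-bleach times in seconds (t = 0 at the first sample).
        y : array-like, shape (n,)
            Normalized intensities.
        """
        t = np.asarray(X, dtype=float).reshape(-1)
        f = np.asarray(y, dtype=float).reshape(-1)
        if t.size != f.size:
            raise ValueError("X and y must have equal length")
        if t.size < 10:
            raise ValueError(f"need >= 10 post-bleach samples, got {t.size}")

        f0_init = float(f[0])
        finf_init = float(np.mean(f[-max(3, t.size // 10):]))
        gain_init = max(finf_init - f0_init, 1e-6)
        # crude halftime guess: first crossing of the half-recovery level
        half_level = f0_init + 0.5 * gain_init
        above = np.nonzero(f >= half_level)[0]
        t_half_init = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(
            t[-1] / 4 + 1e-6
        )

        try:
            popt, _ = curve_fit(
                recovery_model,
                t,
                f,
                p0=[f0_init, gain_init, t_half_init],
                bounds=([0.0, 0.0, 1e-9], [1.2, 1.2, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitNonConvergence(
                f"FRAP recovery fit did not converge: {exc}",
                best_params=(f0_init, gain_init, t_half_init),
            ) from exc

        f0, gain, t_half = map(float, popt)
        resid = f - recovery_model(t, *popt)
        n = t.size
        rss = float(resid @ resid)
        rss_flat = float(np.sum((f - f.mean()) ** 2))
        # AIC comparison against a flat model: flags non-monotone traces
        aic_exp = n * np.log(max(rss, 1e-300) / n) + 2 * 3
        aic_flat = n * np.log(max(rss_flat, 1e-300) / n) + 2 * 1

        self.f0_ = f0
        self.f_inf_ = f0 + gain
        self.t_half_s_ = t_half
        self.mobile_fraction_ = float(np.clip(gain / (1.0 - f0), 0.0, 1.0)) if f0 < 1 else 0.0
        self.residual_norm_ = float(np.sqrt(rss))
        self.flat_model_warning_ = bool(aic_flat < aic_exp)
        self.d_um2_s_ = (
            diffusion_from_halftime(t_half, self.roi_radius_um, self.gamma)
            if self.roi_radius_um is not None
            else None
        )
        return self

    def predict(self, X):
        """Evaluate the fitted recovery curve at times ``X`` (seconds)."""
        t = np.asarray(X, dtype=float).reshape(-1)
        return recovery_model(t, self.f0_, self.f_inf_ - self.f0_, self.t_half_s_)


def fit_recovery(trace: FrapTrace, gamma: float = 0.88) -> FrapFit:
    """Fit the single-exponential recovery of a normalized trace."""
    est = ExponentialRecovery(gamma=gamma, roi_radius_um=trace.roi_radius_um)
    mask = trace.post_mask
    est.fit(trace.time_s[mask], trace.intensity[mask])
    return FrapFit(
        f_pre=1.0,
        f0=est.f0_,
        f_inf=est.f_inf_,
        t_half_s=est.t_half_s_,
        mobile_fraction=est.mobile_fraction_,
        residual_norm=est.residual_norm_,
        d_um2_s=est.d_um2_s_,
        flat_model_warning=est.flat_model_warning_,
    )


def diffusion_from_halftime(t_half_s: float, w_um: float, gamma: float = 0.88) -> float:
    """Lateral diffusion coefficient from the recovery halftime.

    D = gamma * w^2 / (4 * t_half) for a circular bleach spot of radius
    ``w_um``; gamma = 0.88 is the uniform-beam value.
    """
    if t_half_s <= 0:
        raise ValueError(f"t_half_s must be positive, got {t_half_s}")
    if w_um <= 0:
        raise ValueError(f"w_um must be positive, got {w_um}")
    return gamma * w_um**2 / (4.0 * t_half_s)


def halftime_from_diffusion(d_um2_s: float, w_um: float, gamma: float = 0.88) -> float:
    """Inverse of :func:`diffusion_from_halftime` (same relation solved for t_half)."""
    if d_um2_s <= 0:
        raise ValueError(f"d_um2_s must be positive, got {d_um2_s}")
    if w_um <= 0:
        raise ValueError(f"w_um must be positive, got {w_um}")
    return gamma * w_um**2 / (4.0 * d_um2_s)
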