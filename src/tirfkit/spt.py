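"""Single-particle tracking and two-population CPD analysis.

Pipeline: spot enhancement with a discoidal averaging filter (mean over an
inner disk minus mean over a surrounding annulus), local-maximum detection
with sub-pixel refinement by intensity-weighted centroid, greedy
nearest-neighbor trajectory linking, and mobility analysis through the
cumulative probability distribution (CPD) of step sizes.

For 2D Brownian motion the probability that a squared displacement at lag t
stays below r^2 is 1 - exp(-r^2 / (4 D t)); a mixture of a mobile and an
immobile population gives

    P(r^2, t) = 1 - alpha * exp(-r^2 / (4 D1 t)) - (1 - alpha) * exp(-r^2 / (4 D2 t)),

which is fitted to the unbinned empirical CPD by bounded least squares.
Static localization error is not a separate fit parameter: it inflates the
apparent D (4 D t + 4 sigma^2 per step), which is what experiments report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator

from .io import ImageStack, Localization, Trajectory


@dataclass(frozen=True)
class FilterSpec:
    """Discoidal averaging filter radii in pixels (inner disk, outer annulus)."""

    r_inner_px: int = 1
    r_outer_px: int = 3

    def __post_init__(self) -> None:
        if self.r_inner_px < 1:
            raise ValueError("r_inner_px must be >= 1")
        if self.r_outer_px <= self.r_inner_px:
            raise ValueError("r_outer_px must exceed r_inner_px")


@dataclass(frozen=True)
class StepSample:
    """One Euclidean displacement between localizations at a fixed lag."""

    r_um: float
    lag_s: float

    def __post_init__(self) -> None:
        if self.r_um < 0:
            raise ValueError("step size must be non-negative")
        if self.lag_s <= 0:
            raise ValueError("lag must be positive")


@dataclass
class CpdFit:
    """Two-population CPD fit result (diffusion coefficients in um^2/s)."""

    alpha_mobile: float
    d_mobile: float
    d_immobile: float
    residual_norm: float
    n_steps: int
    se_alpha: float = float("nan")
    se_d_mobile: float = float("nan")
    se_d_immobile: float = float("nan")


# ---------------------------------------------------------------------------
# Discoidal filter and detection


def _disk_masks(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    r = spec.r_outer_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.hypot(yy, xx)
    inner = dist <= spec.r_inner_px
    annulus = (dist > spec.r_inner_px) & (dist <= spec.r_outer_px)
    return inner, annulus


class DiscoidalFilter(BaseEstimator):
    """Band-pass spot-enhancement filter (sklearn-style transformer).

    Each output pixel is the mean over the inner disk minus the mean over
    the annulus, with pixel-center distances deciding membership and
    reflected borders.  A constant image maps to zero everywhere.
    """

    def __init__(self, r_inner_px: int = 1, r_outer_px: int = 3):
        self.r_inner_px = r_inner_px
        self.r_outer_px = r_outer_px

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        spec = FilterSpec(self.r_inner_px, self.r_outer_px)
        img = np.asarray(X, dtype=float)
        single = img.ndim == 2
        if single:
            img = img[None]
        k = 2 * spec.r_outer_px + 1
        if img.shape[1] < k or img.shape[2] < k:
            raise ValueError(
                f"image {img.shape[1:]} smaller than the {k}x{k} filter kernel"
            )
        inner, annulus = _disk_masks(spec)
        k_in = inner / inner.sum()
        k_ann = annulus / annulus.sum()
        out = np.stack(
            [
                ndimage.correlate(f, k_in, mode="reflect")
                - ndimage.correlate(f, k_ann, mode="reflect")
                for f in img
            ]
        )
        return out[0] if single else out


def discoidal_filter(image: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the discoidal averaging filter to one 2D image."""
    return DiscoidalFilter(spec.r_inner_px, spec.r_outer_px).transform(image)


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_and_localize(
    stack: ImageStack,
    spec: FilterSpec = FilterSpec(),
    threshold: float = 5.0,
) -> list[Localization]:
    """Detect diffraction-limited spots and localize them to sub-pixel accuracy.

    Candidates are local maxima of the discoidally filtered frame above
    ``threshold`` robust background standard deviations (1.4826 * MAD of the
    filtered frame).  Maxima closer than ``r_outer_px`` are merged keeping
    the brighter one; each survivor is refined by an intensity-weighted
    centroid over a (2*r_outer+1)^2 window of the raw frame (window minimum
    subtracted so a flat background does not pull the centroid).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    px_um = stack.pixel_size_um
    filt = DiscoidalFilter(spec.r_inner_px, spec.r_outer_px)
    half = spec.r_outer_px
    out: list[Localization] = []
    for fi in range(stack.n_frames):
        raw = stack.frames[fi].astype(float)
        resp = filt.transform(raw)
        sd = _robust_sd(resp)
        if sd == 0:  # noise-free background: MAD degenerates, fall back
            sd = float(resp.std())
        if sd == 0:
            continue
        peaks = peak_local_max(
            resp, min_distance=1, threshold_abs=threshold * sd, exclude_border=False
        )
        if peaks.size == 0:
            continue
        # merge duplicates closer than r_outer, keeping the brighter response
        order = np.argsort(-resp[peaks[:, 0], peaks[:, 1]], kind="stable")
        kept: list[np.ndarray] = []
        for idx in order:
            p = peaks[idx]
            if all(np.hypot(*(p - q)) >= spec.r_outer_px for q in kept):
                kept.append(p)
        h, w = raw.shape
        for row, col in kept:
            r0, r1 = max(0, row - half), min(h, row + half + 1)
            c0, c1 = max(0, col - half), min(w, col + half + 1)
            win = raw[r0:r1, c0:c1] - raw[r0:r1, c0:c1].min()
            mass = win.sum()
            if mass <= 0:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cy = float((rr * win).sum() / mass)
            cx = float((cc * win).sum() / mass)
            out.append(Localization(fi, cx * px_um, cy * px_um, float(mass)))
    return out


# ---------------------------------------------------------------------------
# Trajectory linking


def link_trajectories(
    localizations: list[Localization],
    max_step_um: float,
    max_gap_frames: int = 0,
) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of localizations into trajectories.

    For each frame, candidate links from open track ends (within
    ``max_gap_frames`` missed frames) to new localizations are resolved
    globally by ascending distance; links longer than ``max_step_um`` are
    forbidden.  Every localization joins at most one trajectory.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be positive")
    by_frame: dict[int, list[Localization]] = {}
    for loc in localizations:
        by_frame.setdefault(loc.frame_index, []).append(loc)

    tracks: list[list[Localization]] = []
    open_ends: list[int] = []  # indices into tracks
    for frame in sorted(by_frame):
        locs = by_frame[frame]
        candidates = []
        for ti in open_ends:
            last = tracks[ti][-1]
            gap = frame - last.frame_index - 1
            if gap > max_gap_frames:
                continue
            for li, loc in enumerate(locs):
                d = float(np.hypot(loc.x_um - last.x_um, loc.y_um - last.y_um))
                if d <= max_step_um:
                    candidates.append((d, ti, li))
        candidates.sort(key=lambda c: c[0])
        used_tracks: set[int] = set()
        used_locs: set[int] = set()
        for d, ti, li in candidates:
            if ti in used_tracks or li in used_locs:
                continue
            tracks[ti].append(locs[li])
            used_tracks.add(ti)
            used_locs.add(li)
        for li, loc in enumerate(locs):
            if li not in used_locs:
                tracks.append([loc])
        open_ends = [
            ti for ti, tr in enumerate(tracks)
            if frame - tr[-1].frame_index <= max_gap_frames
        ]
    return [Trajectory(id=i, localizations=tr) for i, tr in enumerate(tracks)]


# ---------------------------------------------------------------------------
# Step sizes and CPD


def step_sizes(
    trajectories: list[Trajectory],
    lag_frames: int = 1,
    frame_interval_s: float = 1.0,
) -> list[StepSample]:
    """Euclidean displacements at a fixed frame lag, gap-free pairs only."""
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    lag_s = lag_frames * frame_interval_s
    out: list[StepSample] = []
    for tr in trajectories:
        frames = tr.frames()
        pos = tr.positions_um()
        index_of = {int(f): i for i, f in enumerate(frames)}
        for f, i in index_of.items():
            j = index_of.get(f + lag_frames)
            if j is None:
                continue
            # reject pairs spanning a bridged gap: all intermediate frames present
            if any(f + k not in index_of for k in range(1, lag_frames)):
                continue
            out.append(StepSample(float(np.linalg.norm(pos[j] - pos[i])), lag_s))
    return out


def empirical_cpd(steps: list[StepSample]) -> np.ndarray:
    """Unbinned empirical CPD of squared step sizes.

    Returns an (n, 2) array of (r^2, P) at the sorted sample points, with
    P(r^2) the fraction of samples <= r^2 (so P runs from 1/n to 1).
    """
    if len(steps) < 10:
        raise ValueError(f"need >= 10 steps for an empirical CPD, got {len(steps)}")
    lags = {s.lag_s for s in steps}
    if len(lags) > 1:
        raise ValueError(f"steps mix lags {sorted(lags)}; one lag per CPD")
    r2 = np.sort(np.array([s.r_um for s in steps]) ** 2)
    p = np.arange(1, r2.size + 1) / r2.size
    return np.column_stack([r2, p])


# ---------------------------------------------------------------------------
# Two-population fit


def _cpd_model(r2, alpha, d1, d2, lag_s):
    t4 = 4.0 * lag_s
    return (
        1.0
        - alpha * np.exp(-r2 / np.maximum(t4 * d1, 1e-300))
        - (1.0 - alpha) * np.exp(-r2 / np.maximum(t4 * d2, 1e-300))
    )


class TwoPopulationCpd(BaseEstimator):
    """Two-population mobility fit on step sizes (sklearn-style estimator).

    ``fit(X)`` takes step sizes in micrometers (shape (n,) or (n, 1)),
    builds the unbinned empirical CPD of squared steps, and least-squares
    fits the bounded mixture model.  Parameter uncertainties come from a
    seeded bootstrap over steps (``n_boot`` resamples, default 200).

    Parameters
    ----------
    lag_s : float
        Time lag of the steps, seconds.
    fix_alpha : float or None
        If set, the mobile fraction is pinned (1.0 gives the
        single-population model 1 - exp(-r^2/(4 D t))).
    n_boot : int
        Bootstrap resamples for standard errors; 0 disables.
    random_state : int
        Seed of the bootstrap resampler.

    Attributes
    ----------
    alpha_mobile_, d_mobile_, d_immobile_ : float
        Mixture weight and apparent diffusion coefficients (um^2/s),
        ordered so d_mobile_ >= d_immobile_.
    se_alpha_, se_d_mobile_, se_d_immobile_ : float
    residual_norm_, n_steps_ : float, int
    """

    MIN_STEPS = 50

    def __init__(
        self,
        lag_s: float = 10.0,
        fix_alpha: float | None = None,
        n_boot: int = 200,
        random_state: int = 0,
        init: tuple[float, float, float] | None = None,
    ):
        self.lag_s = lag_s
        self.fix_alpha = fix_alpha
        self.n_boot = n_boot
        self.random_state = random_state
        self.init = init

    def fit(self, X, y=None):
        r = np.asarray(X, dtype=float).reshape(-1)
        if r.size < self.MIN_STEPS:
            raise ValueError(
                f"need >= {self.MIN_STEPS} steps for the two-population fit, "
                f"got {r.size}"
            )
        r2 = np.sort(r**2)
        p = np.arange(1, r2.size + 1) / r2.size
        alpha, d1, d2, resid = self._fit_curve(r2, p)
        self.alpha_mobile_, self.d_mobile_, self.d_immobile_ = alpha, d1, d2
        self.residual_norm_ = resid
        self.n_steps_ = int(r.size)
        if self.n_boot > 0:
            rng = np.random.default_rng(self.random_state)
            boots = []
            for _ in range(self.n_boot):
                rb = rng.choice(r, size=r.size, replace=True)
                r2b = np.sort(rb**2)
                pb = np.arange(1, r2b.size + 1) / r2b.size
                try:
                    a, b1, b2, _ = self._fit_curve(r2b, pb, p0=(alpha, d1, d2))
                except RuntimeError:
                    continue
                boots.append((a, b1, b2))
            if len(boots) >= 2:
                se = np.std(np.array(boots), axis=0, ddof=1)
                self.se_alpha_, self.se_d_mobile_, self.se_d_immobile_ = map(float, se)
            else:  # pragma: no cover - pathological bootstrap
                self.se_alpha_ = self.se_d_mobile_ = self.se_d_immobile_ = float("nan")
        else:
            self.se_alpha_ = self.se_d_mobile_ = self.se_d_immobile_ = float("nan")
        return self

    def _fit_curve(self, r2, p, p0=None):
        t = self.lag_s
        if p0 is None:
            p0 = self.init
        if self.fix_alpha is not None:
            alpha = float(self.fix_alpha)
            d1_0 = p0[1] if p0 else float(np.median(r2)) / (4 * t * np.log(2.0))
            if alpha == 1.0:  # single-population closed form; d2 unidentifiable
                popt, _ = curve_fit(
                    lambda x, d1: 1.0 - np.exp(-x / np.maximum(4 * t * d1, 1e-300)),
                    r2,
                    p,
                    p0=[max(d1_0, 1e-12)],
                    bounds=(0.0, np.inf),
                    maxfev=20000,
                )
                d1 = float(popt[0])
                resid = p - (1.0 - np.exp(-r2 / np.maximum(4 * t * d1, 1e-300)))
                return alpha, d1, 0.0, float(np.linalg.norm(resid))
            d2_0 = p0[2] if p0 else max(float(np.percentile(r2, 10)) / (4 * t), 1e-9)
            popt, _ = curve_fit(
                lambda x, d1, d2: _cpd_model(x, alpha, d1, d2, t),
                r2,
                p,
                p0=[max(d1_0, 1e-12), d2_0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
            d1, d2 = map(float, popt)
            if d2 > d1:
                d1, d2 = d2, d1
            resid = p - _cpd_model(r2, alpha, d1, d2, t)
            return alpha, d1, d2, float(np.linalg.norm(resid))
        if p0 is None:
            # moment-flavored start: fast population from the upper tail,
            # slow population from the lower tail of squared steps
            d1_0 = float(np.percentile(r2, 90)) / (4 * t)
            d2_0 = max(float(np.percentile(r2, 10)) / (4 * t), 1e-9)
            p0 = (0.5, d1_0, d2_0)
        try:
            popt, _ = curve_fit(
                lambda x, a, d1, d2: _cpd_model(x, a, d1, d2, t),
                r2,
                p,
                p0=list(p0),
                bounds=([0.0, 0.0, 0.0], [1.0, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"two-population CPD fit did not converge (start {p0}): {exc}"
            ) from exc
        alpha, d1, d2 = map(float, popt)
        if d2 > d1:  # enforce the mobile-first convention
            alpha, d1, d2 = 1.0 - alpha, d2, d1
        resid = p - _cpd_model(r2, alpha, d1, d2, t)
        return alpha, d1, d2, float(np.linalg.norm(resid))

    def predict(self, X):
        """Model CPD evaluated at squared displacements ``X`` (um^2)."""
        r2 = np.asarray(X, dtype=float).reshape(-1)
        return _cpd_model(
            r2, self.alpha_mobile_, self.d_mobile_, max(self.d_immobile_, 1e-12), self.lag_s
        )


def fit_cpd_two_population(
    cpd: np.ndarray,
    lag_s: float,
    init: tuple[float, float, float] | None = None,
    n_boot: int = 200,
    random_state: int = 0,
) -> CpdFit:
    """Fit the two-population model to a CPD given as (r^2, P) pairs.

    The provided ordinates are fitted as-is, so an analytic tabulated curve
    is recovered exactly.  When ``cpd`` comes from :func:`empirical_cpd`
    each row is one step; the bootstrap (``n_boot`` resamples) resamples
    rows and recomputes ranks.  Set ``n_boot=0`` for non-sample curves.
    """
    cpd = np.asarray(cpd, dtype=float)
    if cpd.ndim != 2 or cpd.shape[1] != 2:
        raise ValueError("cpd must be an (n, 2) array of (r^2, P)")
    if cpd.shape[0] < TwoPopulationCpd.MIN_STEPS:
        raise ValueError(
            f"need >= {TwoPopulationCpd.MIN_STEPS} CPD points, got {cpd.shape[0]}"
        )
    est = TwoPopulationCpd(
        lag_s=lag_s, init=init, n_boot=0, random_state=random_state
    )
    alpha, d1, d2, resid = est._fit_curve(cpd[:, 0], cpd[:, 1])
    se = (float("nan"),) * 3
    if n_boot > 0:
        rng = np.random.default_rng(random_state)
        r = np.sqrt(cpd[:, 0])
        boots = []
        for _ in range(n_boot):
            rb = rng.choice(r, size=r.size, replace=True)
            r2b = np.sort(rb**2)
            pb = np.arange(1, r2b.size + 1) / r2b.size
            try:
                a, b1, b2, _ = est._fit_curve(r2b, pb, p0=(alpha, d1, d2))
            except RuntimeError:
                continue
            boots.append((a, b1, b2))
        if len(boots) >= 2:
            se = tuple(np.std(np.array(boots), axis=0, ddof=1))
    return CpdFit(
        alpha_mobile=alpha,
        d_mobile=d1,
        d_immobile=d2,
        residual_norm=resid,
        n_steps=int(cpd.shape[0]),
        se_alpha=float(se[0]),
        se_d_mobile=float(se[1]),
        se_d_immobile=float(se[2]),
    )
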