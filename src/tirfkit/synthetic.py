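"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here: brightfield-like movies of cells
undergoing rigid per-frame translation, fluorescence movies of point emitters
diffusing as a two-population (mobile + immobile) mixture, static
eisosome-marker centroid fields with molecules placed at controlled distances,
and FRAP recovery traces.  Each generator is a pure function of its
configuration and seed, and returns a :class:`GroundTruth` record of every
generating parameter so that recovery tests have an exact oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frap import FrapTrace
from .io import ImageStack, Localization, Trajectory


@dataclass
class SimConfig:
    """Acquisition settings for simulated movies.

    Defaults mirror a typical EMCCD TIRF acquisition: 80 nm pixels, 100 ms
    frames, 50 frames.  ``spot_intensity`` (integrated counts per emitter) and
    ``noise_sd`` (additive Gaussian camera noise) are free choices, since
    camera statistics beyond the EM gain are not specified for the emulated
    experiments.
    """

    seed: int = 0
    pixel_size_nm: float = 80.0
    frame_interval_s: float = 0.1
    n_frames: int = 50
    image_shape: tuple[int, int] = (128, 128)
    noise_sd: float = 5.0
    psf_sigma_px: float = 1.3
    spot_intensity: float = 2000.0
    boundary: str = "periodic"  # or "zero"

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.boundary not in ("periodic", "zero"):
            raise ValueError(f"boundary must be 'periodic' or 'zero', got {self.boundary!r}")


@dataclass
class TwoPopulationParams:
    """Generating parameters of the two-population lateral-diffusion model.

    By convention the first population is the faster ("mobile") one.  The
    immobile population keeps a small positive coefficient by default since a
    strictly zero D degenerates the downstream mixture fit.  ``loc_error_nm``
    is a static per-axis localization error added to every stored coordinate.
    """

    alpha_mobile: float = 0.57
    d_mobile_um2_s: float = 5.1e-4
    d_immobile_um2_s: float = 1e-5
    loc_error_nm: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_mobile <= 1.0:
            raise ValueError("alpha_mobile must be in [0, 1]")
        if self.d_mobile_um2_s < 0 or self.d_immobile_um2_s < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.d_mobile_um2_s < self.d_immobile_um2_s:
            raise ValueError("d_mobile_um2_s must be >= d_immobile_um2_s")
        if self.loc_error_nm < 0:
            raise ValueError("loc_error_nm must be non-negative")


@dataclass
class GroundTruth:
    """Record of every generating parameter of one simulated artifact."""

    kind: str
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "params": _jsonable(self.params)}, fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# Drifting-cell movies


def _cell_scene(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """A brightfield-like scene: smooth disk-shaped cells on a flat background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    scene = np.full(shape, 100.0)
    n_cells = max(3, (h * w) // 2000)
    for _ in range(n_cells):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(4.0, 8.0)
        amp = rng.uniform(200.0, 600.0)
        # periodic placement keeps the scene consistent with circular shifts
        dy = np.minimum(np.abs(yy - cy), h - np.abs(yy - cy))
        dx = np.minimum(np.abs(xx - cx), w - np.abs(xx - cx))
        scene += amp * np.exp(-(dy**2 + dx**2) / (2 * (r / 2) ** 2))
    return scene


def simulate_drifting_cells(
    config: SimConfig, shifts: list[tuple[int, int]]
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a movie of cells rigidly translated between frames.

    ``shifts[k]`` is the integer (dx, dy) translation from frame k to frame
    k+1 (x = columns, y = rows).  Periodic boundaries (default) keep the FFT
    correlation oracle exact; ``config.boundary = 'zero'`` rolls in zeros.
    Fresh Gaussian noise is added to every frame.
    """
    if len(shifts) != config.n_frames - 1:
        raise ValueError(
            f"need n_frames - 1 = {config.n_frames - 1} shifts, got {len(shifts)}"
        )
    h, w = config.image_shape
    for k, (dx, dy) in enumerate(shifts):
        if abs(dx) >= w / 4 or abs(dy) >= h / 4:
            raise ValueError(
                f"shift {(dx, dy)} for frame pair {k} exceeds a quarter of the "
                f"image dimensions {config.image_shape}"
            )
    rng = np.random.default_rng(config.seed)
    scene = _cell_scene(rng, (h, w))
    frames = np.empty((config.n_frames, h, w))
    current = scene
    frames[0] = current
    for k, (dx, dy) in enumerate(shifts):
        if config.boundary == "periodic":
            current = np.roll(current, shift=(dy, dx), axis=(0, 1))
        else:
            current = ndimage.shift(current, (dy, dx), order=0, mode="constant", cval=0.0)
        frames[k + 1] = current
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    stack = ImageStack(frames, config.pixel_size_nm, config.frame_interval_s)
    gt = GroundTruth(
        kind="drifting_cells",
        params={"shifts": [list(s) for s in shifts], "config": config},
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Two-population Brownian trajectories


def simulate_trajectories(
    params: TwoPopulationParams,
    n_particles: int,
    n_steps: int,
    dt_s: float,
    seed: int,
    start_box_um: tuple[float, float] | None = None,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate 2D Brownian trajectories from the two-population mixture.

    Each particle is mobile with probability ``alpha_mobile``; per-axis
    displacements per step are N(0, 2*D*dt) and a static localization error
    of ``loc_error_nm`` per axis is added independently to every stored
    position.  Starting positions are uniform over ``start_box_um``
    (default: a box wide enough that particles rarely approach each other).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt_s <= 0:
        raise ValueError(f"dt_s must be positive, got {dt_s}")
    rng = np.random.default_rng(seed)
    if start_box_um is None:
        side = max(2.0, 2.0 * np.sqrt(n_particles))
        start_box_um = (side, side)
    labels = rng.random(n_particles) < params.alpha_mobile
    sigma_loc = params.loc_error_nm / 1000.0
    trajectories: list[Trajectory] = []
    true_positions = []
    for i in range(n_particles):
        d = params.d_mobile_um2_s if labels[i] else params.d_immobile_um2_s
        start = rng.uniform([0, 0], start_box_um)
        steps = rng.normal(0.0, np.sqrt(2.0 * d * dt_s), size=(n_steps, 2))
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        obs = pos + rng.normal(0.0, sigma_loc, size=pos.shape) if sigma_loc > 0 else pos
        trajectories.append(
            Trajectory(
                id=i,
                localizations=[
                    Localization(t, float(x), float(y)) for t, (x, y) in enumerate(obs)
                ],
            )
        )
        true_positions.append(pos)
    gt = GroundTruth(
        kind="two_population_trajectories",
        params={
            "params": params,
            "dt_s": dt_s,
            "mobile_labels": labels.tolist(),
            "true_positions_um": true_positions,
            "seed": seed,
        },
    )
    return trajectories, gt


# ---------------------------------------------------------------------------
# Rendering emitters into movies


def render_particle_movie(trajectories: list[Trajectory], config: SimConfig) -> ImageStack:
    """Render localizations as isotropic Gaussian spots with camera noise.

    Each localization becomes a 2D Gaussian of sigma ``psf_sigma_px`` whose
    pixel-summed mass equals ``spot_intensity`` (up to truncation at the
    frame edge and at the +-5 sigma render window).
    """
    h, w = config.image_shape
    px = config.pixel_size_nm / 1000.0
    n_frames = 1 + max(
        (loc.frame_index for tr in trajectories for loc in tr.localizations), default=-1
    )
    if n_frames < 1:
        raise ValueError("no localizations to render")
    frames = np.zeros((n_frames, h, w))
    sig = config.psf_sigma_px
    half = int(np.ceil(5 * sig))
    for tr in trajectories:
        for loc in tr.localizations:
            col = loc.x_um / px
            row = loc.y_um / px
            if not (-0.5 <= col < w - 0.5 and -0.5 <= row < h - 0.5):
                raise ValueError(
                    f"trajectory {tr.id}, frame {loc.frame_index}: emitter at "
                    f"({loc.x_um:.3f}, {loc.y_um:.3f}) um is outside the image"
                )
            r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 2)
            c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 2)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            spot = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sig**2))
            frames[loc.frame_index, r0:r1, c0:c1] += (
                config.spot_intensity / (2 * np.pi * sig**2)
            ) * spot
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    return ImageStack(frames, config.pixel_size_nm, config.frame_interval_s)


# ---------------------------------------------------------------------------
# FRAP traces


def simulate_frap_trace(
    pre_level: float,
    bleach_depth: float,
    mobile_fraction: float,
    t_half_s: float,
    n_pre: int = 20,
    n_post: int = 100,
    dt_s: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    roi_radius_um: float = 0.5,
) -> tuple[FrapTrace, GroundTruth]:
    """Simulate a FRAP trace: pre-bleach plateau, instantaneous bleach,
    single-exponential recovery, additive Gaussian noise.

    The post-bleach curve is F(t) = F0 + (Finf - F0)*(1 - exp(-ln2*t/t_half))
    with F0 = pre_level*(1 - bleach_depth) and
    Finf = F0 + mobile_fraction*(pre_level - F0).
    """
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if t_half_s <= 0:
        raise ValueError(f"t_half_s must be positive, got {t_half_s}")
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    if n_post < 3:
        raise ValueError("n_post must be >= 3")
    f0 = pre_level * (1.0 - bleach_depth)
    f_inf = f0 + mobile_fraction * (pre_level - f0)
    t_pre = np.arange(-n_pre, 0) * dt_s
    t_post = np.arange(n_post) * dt_s
    intensity = np.concatenate(
        [
            np.full(n_pre, pre_level),
            f0 + (f_inf - f0) * (1.0 - np.exp(-np.log(2.0) * t_post / t_half_s)),
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    trace = FrapTrace(
        time_s=np.concatenate([t_pre, t_post]),
        intensity=intensity,
        n_pre=n_pre,
        roi_radius_um=roi_radius_um,
    )
    gt = GroundTruth(
        kind="frap_trace",
        params={
            "pre_level": pre_level,
            "bleach_depth": bleach_depth,
            "mobile_fraction": mobile_fraction,
            "t_half_s": t_half_s,
            "f0": f0,
            "f_inf": f_inf,
            "n_pre": n_pre,
            "n_post": n_post,
            "dt_s": dt_s,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return trace, gt


# ---------------------------------------------------------------------------
# Eisosome centroid fields


@dataclass
class Placement:
    """Distance distribution of molecules around their assigned centroid.

    ``kind`` is one of ``fixed`` (all at ``distance_um``), ``uniform``
    (uniform on [low_um, high_um]) or ``gaussian`` (|N(mean_um, sd_um)|).
    Angles are always uniform on [0, 2*pi).
    """

    kind: str = "fixed"
    distance_um: float = 0.2
    low_um: float = 0.0
    high_um: float = 0.4
    mean_um: float = 0.2
    sd_um: float = 0.05

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.distance_um)
        if self.kind == "uniform":
            return rng.uniform(self.low_um, self.high_um, size=n)
        if self.kind == "gaussian":
            return np.abs(rng.normal(self.mean_um, self.sd_um, size=n))
        raise ValueError(f"unknown placement kind {self.kind!r}")


def simulate_eisosome_field(
    n_eisosomes: int,
    n_molecules: int,
    field_size_um: tuple[float, float],
    placement: Placement,
    seed: int,
    min_separation_um: float = 0.5,
    max_attempts: int = 10000,
) -> tuple[np.ndarray, list[Localization], GroundTruth]:
    """Place eisosome centroids with a minimum separation, then scatter
    molecules at controlled distances around randomly assigned centroids.

    Returns (centroids (n, 2) in um, molecule localizations, ground truth).
    """
    if n_eisosomes < 1:
        raise ValueError("n_eisosomes must be >= 1")
    rng = np.random.default_rng(seed)
    fx, fy = field_size_um
    centroids: list[np.ndarray] = []
    attempts = 0
    while len(centroids) < n_eisosomes:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_eisosomes} centroids with separation "
                f">= {min_separation_um} um in a {fx} x {fy} um field after "
                f"{max_attempts} attempts"
            )
        cand = rng.uniform([0, 0], [fx, fy])
        attempts += 1
        if all(np.linalg.norm(cand - c) >= min_separation_um for c in centroids):
            centroids.append(cand)
    cent = np.array(centroids)
    assignment = rng.integers(0, n_eisosomes, size=n_molecules)
    dist = placement.sample(rng, n_molecules)
    theta = rng.uniform(0.0, 2 * np.pi, size=n_molecules)
    xy = cent[assignment] + np.column_stack([dist * np.cos(theta), dist * np.sin(theta)])
    molecules = [Localization(0, float(x), float(y)) for x, y in xy]
    gt = GroundTruth(
        kind="eisosome_field",
        params={
            "centroids_um": cent,
            "assigned_centroid": assignment.tolist(),
            "true_distance_um": dist.tolist(),
            "placement": placement,
            "seed": seed,
        },
    )
    return cent, molecules, gt
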