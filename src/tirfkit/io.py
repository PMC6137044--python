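"""File formats and shared spatial types.

Coordinate convention (used everywhere in the package): ``x`` is the column
direction, ``y`` the row direction, and the origin sits at the *center* of
pixel ``(row=0, col=0)``.  Physical coordinates are micrometers; pixels appear
only inside image-processing internals.  Frame indices are 0-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Documented default pixel size for metadata-less stacks (EMCCD, 100x TIRF).
DEFAULT_PIXEL_SIZE_NM = 80.0
DEFAULT_FRAME_INTERVAL_S = 0.1

LOCALIZATION_COLUMNS = ["trajectory_id", "frame", "x_um", "y_um", "intensity"]


@dataclass
class ImageStack:
    """An ordered stack of 2D grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Non-negative pixel intensities (camera counts).
    pixel_size_nm : float
        Physical edge length of one pixel, nanometers.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    """

    frames: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, h, w) array, got shape {self.frames.shape}"
            )
        if self.n_frames < 1:
            raise ValueError("an ImageStack needs at least one frame")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        if self.frame_interval_s <= 0:
            raise ValueError(
                f"frame_interval_s must be positive, got {self.frame_interval_s}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


@dataclass(frozen=True)
class Localization:
    """A single sub-pixel emitter position on one frame."""

    frame_index: int
    x_um: float
    y_um: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError("localization coordinates must be finite")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class Trajectory:
    """Time-ordered localizations of one tracked particle."""

    id: int
    localizations: list[Localization] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [loc.frame_index for loc in self.localizations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(
                f"trajectory {self.id}: frame indices must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.localizations)

    def positions_um(self) -> np.ndarray:
        """Return an (n, 2) array of (x, y) in micrometers."""
        return np.array([[p.x_um, p.y_um] for p in self.localizations]).reshape(-1, 2)

    def frames(self) -> np.ndarray:
        return np.array([p.frame_index for p in self.localizations], dtype=int)


# ---------------------------------------------------------------------------
# TIFF image stacks


def write_stack(stack: ImageStack, path, dtype=np.uint16) -> None:
    """Write a multi-page grayscale TIFF plus a JSON metadata sidecar."""
    frames = stack.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.rint(frames), info.min, info.max).astype(dtype)
    else:
        frames = frames.astype(dtype)
    tifffile.imwrite(
        str(path),
        frames,
        photometric="minisblack",
        metadata={
            "pixel_size_nm": stack.pixel_size_nm,
            "frame_interval_s": stack.frame_interval_s,
        },
    )
    _sidecar(path).write_text(
        json.dumps(
            {
                "pixel_size_nm": stack.pixel_size_nm,
                "frame_interval_s": stack.frame_interval_s,
            }
        )
    )


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or any grayscale TIFF).

    Metadata is taken from the JSON sidecar if present, else from the TIFF
    description; missing fields fall back to documented defaults (pixel size
    80 nm, frame interval 0.1 s) with a logged warning.
    """
    try:
        frames = tifffile.imread(str(path))
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"not a readable TIFF file: {path}") from exc
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        try:
            with tifffile.TiffFile(str(path)) as tf:
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        except Exception:  # pragma: no cover - malformed embedded metadata
            meta = {}
    if "pixel_size_nm" not in meta or "frame_interval_s" not in meta:
        warnings.warn(
            f"{path}: missing acquisition metadata; applying defaults "
            f"(pixel_size_nm={DEFAULT_PIXEL_SIZE_NM}, "
            f"frame_interval_s={DEFAULT_FRAME_INTERVAL_S})",
            stacklevel=2,
        )
    return ImageStack(
        frames=np.asarray(frames),
        pixel_size_nm=float(meta.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM)),
        frame_interval_s=float(meta.get("frame_interval_s", DEFAULT_FRAME_INTERVAL_S)),
    )


def _sidecar(path):
    from pathlib import Path

    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


# ---------------------------------------------------------------------------
# Localization / trajectory tables (CSV)


def write_localizations(items, path) -> None:
    """Write localizations or trajectories to CSV.

    Accepts either a flat list of :class:`Localization` (trajectory_id -1) or
    a list of :class:`Trajectory`.  Coordinates are stored with 6 decimal
    places (sub-nanometer in micrometers), which bounds the round-trip error.
    """
    rows = []
    for item in items:
        if isinstance(item, Trajectory):
            for loc in item.localizations:
                rows.append((item.id, loc.frame_index, loc.x_um, loc.y_um, loc.intensity))
        else:
            rows.append((-1, item.frame_index, item.x_um, item.y_um, item.intensity))
    df = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_localizations(path, as_trajectories: bool | None = None):
    """Read a localization CSV.

    Returns a list of :class:`Trajectory` if the table carries trajectory ids
    (any id >= 0), else a flat list of :class:`Localization`.  Set
    ``as_trajectories`` to force either view.
    """
    df = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns and c != "intensity"]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "intensity" not in df.columns:
        df["intensity"] = 0.0
    dup = df.duplicated(subset=["trajectory_id", "frame"])
    if dup.any() and (df.loc[dup, "trajectory_id"] >= 0).any():
        bad = df.loc[dup & (df["trajectory_id"] >= 0)].iloc[0]
        raise ValueError(
            f"duplicate (trajectory_id, frame) row: "
            f"({int(bad.trajectory_id)}, {int(bad.frame)})"
        )
    if as_trajectories is None:
        as_trajectories = bool((df["trajectory_id"] >= 0).any())
    if not as_trajectories:
        return [
            Localization(int(r.frame), float(r.x_um), float(r.y_um), float(r.intensity))
            for r in df.itertuples()
        ]
    out = []
    for tid, sub in df.groupby("trajectory_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(
            Trajectory(
                id=int(tid),
                localizations=[
                    Localization(int(r.frame), float(r.x_um), float(r.y_um), float(r.intensity))
                    for r in sub.itertuples()
                ],
            )
        )
    return out
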