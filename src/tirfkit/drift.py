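"""Frame-to-frame cell-movement quantification by FFT cross-correlation.

The circular cross-correlation of two frames is computed with forward and
inverse FFTs; the integer shift maximizing it is reported in signed form
within (-N/2, N/2].  Each frame is mean-subtracted before the FFT to
suppress the DC peak; no windowing is applied.  Detection is integer-pixel
by design — movement is reported in whole pixels, as is customary for
judging whether a cell is immobile at the camera's resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import ImageStack


@dataclass(frozen=True)
class Roi:
    """A rectangle in pixel coordinates: origin (x0, y0), size (w, h)."""

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"ROI must have positive size, got {self.w}x{self.h}")


@dataclass
class MovementTrace:
    """Per-frame-pair integer shifts (dx, dy) within a ROI."""

    shifts_px: np.ndarray  # (n_pairs, 2) of (dx, dy)
    roi: Roi
    n_pairs: int


def cross_correlate_pair(frame_a: np.ndarray, frame_b: np.ndarray) -> tuple[int, int]:
    """Integer (dx, dy) shift of ``frame_b`` relative to ``frame_a``.

    Returns the argmax of the circular cross-correlation, i.e. the shift s
    such that frame_b ~= frame_a circularly translated by s (dx along
    columns, dy along rows).  Ties are broken by the lexicographically
    smallest signed (dy, dx).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("no correlation peak: both frames are constant")
    a = a - a.mean()
    b = b - b.mean()
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    peaks = np.argwhere(corr == corr.max())
    h, w = a.shape
    signed = np.column_stack(
        [
            np.where(peaks[:, 0] > h // 2, peaks[:, 0] - h, peaks[:, 0]),
            np.where(peaks[:, 1] > w // 2, peaks[:, 1] - w, peaks[:, 1]),
        ]
    )
    order = np.lexsort((signed[:, 1], signed[:, 0]))
    dy, dx = signed[order[0]]
    return int(dx), int(dy)


class DriftEstimator(BaseEstimator):
    """Movement quantification over an image stack (sklearn-style transformer).

    ``transform`` maps a stack (or a (n, h, w) array) to an (n-1, 2) array of
    integer per-pair shifts within the configured ROI.
    """

    def __init__(self, roi: Roi | None = None):
        self.roi = roi

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        frames = X.frames if isinstance(X, ImageStack) else np.asarray(X, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("need a (n>=2, h, w) stack to quantify movement")
        h, w = frames.shape[1:]
        roi = self.roi or Roi(0, 0, w, h)
        if roi.x0 < 0 or roi.y0 < 0 or roi.x0 + roi.w > w or roi.y0 + roi.h > h:
            raise ValueError(f"ROI {roi} outside frame bounds {(h, w)}")
        sub = frames[:, roi.y0 : roi.y0 + roi.h, roi.x0 : roi.x0 + roi.w]
        return np.array(
            [cross_correlate_pair(sub[k], sub[k + 1]) for k in range(len(sub) - 1)],
            dtype=int,
        )


def quantify_movement(stack: ImageStack, roi: Roi | None = None) -> MovementTrace:
    """Apply :func:`cross_correlate_pair` to each consecutive frame pair of a
    stack, restricted to ``roi`` (default: full frame)."""
    shifts = DriftEstimator(roi=roi).transform(stack)
    h, w = stack.frame_shape
    return MovementTrace(
        shifts_px=shifts, roi=roi or Roi(0, 0, w, h), n_pairs=shifts.shape[0]
    )


def movement_summary(trace: MovementTrace) -> dict:
    """Tabular summary of a movement trace (max excursions, zero fraction)."""
    if trace.n_pairs < 1:
        raise ValueError("movement trace has no frame pairs")
    s = trace.shifts_px
    return {
        "max_abs_dx_px": int(np.max(np.abs(s[:, 0]))),
        "max_abs_dy_px": int(np.max(np.abs(s[:, 1]))),
        "zero_fraction": float(np.mean(np.all(s == 0, axis=1))),
        "n_pairs": trace.n_pairs,
        "dx_px": s[:, 0].tolist(),
        "dy_px": s[:, 1].tolist(),
    }
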