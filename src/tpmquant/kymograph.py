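"""Kymographs along a cell's long axis.

A kymograph stacks, column by column, the intensity profile sampled
along a fixed line at successive timepoints, turning motion along the
line (e.g. tropomyosin cables flowing toward the division site) into
sloped ridges whose slope is the velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class AxisLine:
    """A sampling line with an odd perpendicular averaging width."""

    start: tuple[float, float]  # (x, y), px
    end: tuple[float, float]
    width: int = 5

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("line length must be > 0")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("sampling width must be odd and >= 1")

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))


@dataclass
class Kymograph:
    data: np.ndarray  # (position, time)
    um_per_px: float
    s_per_frame: float
    line: AxisLine


def cell_long_axis(mask: np.ndarray, width: int = 5) -> AxisLine:
    """Long axis of a cell mask from its pixel second moments.

    The line runs through the centroid along the principal direction of
    the pixel covariance, clipped to the mask's extent.  Orientation is
    canonical: angle in [0, pi), first endpoint at smaller x (ties:
    smaller y).  Near-isotropic masks (aspect < 1.2) warn but still
    return a diameter.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size < 10:
        raise ValueError(f"mask has only {ys.size} pixels; need >= 10")
    xc, yc = xs.mean(), ys.mean()
    cov = np.cov(np.stack([xs - xc, ys - yc]).astype(float)) + 1e-12 * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    aspect = np.sqrt(evals[1] / max(evals[0], 1e-12))
    if aspect < 1.2:
        warnings.warn(
            f"mask is nearly isotropic (aspect {aspect:.2f}); long axis is "
            "poorly defined",
            RuntimeWarning,
            stacklevel=2,
        )
    vx, vy = evecs[:, 1]
    ang = np.arctan2(vy, vx) % np.pi
    d = np.array([np.cos(ang), np.sin(ang)])
    proj = (xs - xc) * d[0] + (ys - yc) * d[1]
    p0 = np.array([xc, yc]) + proj.min() * d
    p1 = np.array([xc, yc]) + proj.max() * d
    if (p0[0], p0[1]) > (p1[0], p1[1]):
        p0, p1 = p1, p0
    return AxisLine(start=(float(p0[0]), float(p0[1])), end=(float(p1[0]), float(p1[1])), width=width)


def build_kymograph(
    series: np.ndarray,
    line: AxisLine,
    um_per_px: float = 1.0,
    s_per_frame: float = 1.0,
    mask: np.ndarray | None = None,
) -> Kymograph:
    """Sample a time series along a line into a position x time raster.

    ``series`` is (T, Y, X).  Intensity is bilinearly interpolated at
    unit steps along the line and averaged over ``line.width`` parallel
    offsets perpendicular to it.  With ``mask`` given, intensity outside
    the mask is zeroed before sampling (segmented-signal mode).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3 or series.shape[0] == 0:
        raise ValueError("series must be a nonempty (T, Y, X) array")
    n_pos = int(np.ceil(line.length))
    t_hat = (
        np.array([line.end[0] - line.start[0], line.end[1] - line.start[1]])
        / line.length
    )
    n_hat = np.array([-t_hat[1], t_hat[0]])
    steps = np.arange(n_pos)
    offsets = np.arange(line.width) - line.width // 2
    # sample coordinates: (n_pos, n_offsets), x and y separately
    x = line.start[0] + steps[:, None] * t_hat[0] + offsets[None, :] * n_hat[0]
    y = line.start[1] + steps[:, None] * t_hat[1] + offsets[None, :] * n_hat[1]
    h, w = series.shape[1:]
    if x.min() < -0.5 or y.min() < -0.5 or x.max() > w - 0.5 or y.max() > h - 0.5:
        raise ValueError(
            f"sampling line exits the image: x in [{x.min():.1f}, {x.max():.1f}], "
            f"y in [{y.min():.1f}, {y.max():.1f}], image {w}x{h}"
        )
    kymo = np.empty((n_pos, series.shape[0]))
    for t, frame in enumerate(series):
        if mask is not None:
            frame = np.where(mask, frame, 0.0)
        vals = map_coordinates(frame, [y.ravel(), x.ravel()], order=1, mode="nearest")
        kymo[:, t] = vals.reshape(x.shape).mean(axis=1)
    return Kymograph(data=kymo, um_per_px=um_per_px, s_per_frame=s_per_frame, line=line)


def ridge_velocity(kymo: Kymograph) -> tuple[float, np.ndarray]:
    """Velocity (px/frame) of the brightest ridge, by per-column argmax
    with sub-pixel parabolic refinement and a linear fit over time."""
    data = kymo.data
    pos = np.empty(data.shape[1])
    for t in range(data.shape[1]):
        col = data[:, t]
        i = int(np.argmax(col))
        if 0 < i < len(col) - 1:
            denom = col[i - 1] - 2 * col[i] + col[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (col[i - 1] - col[i + 1]) / denom
            pos[t] = i + np.clip(delta, -0.5, 0.5)
        else:
            pos[t] = i
    slope = float(np.polyfit(np.arange(data.shape[1]), pos, 1)[0])
    return slope, pos
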