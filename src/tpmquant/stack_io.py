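"""Calibrated image-stack I/O and the standard preprocessing steps.

Stacks are held as 5D arrays indexed ``(time, channel, z, y, x)`` with
physical calibration attached (pixel size in nm, z-step in µm, frame
interval in s).  The module provides z-projection (average for
quantification, maximum for display/kymographs), photobleaching
correction of time series, and translation-only registration of the two
camera channels by cross-correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy.optimize import curve_fit
from skimage.registration import phase_cross_correlation

AXES = "TCZYX"


@dataclass
class ImageStack:
    """An intensity raster with physical calibration.

    ``data`` is always stored 5D as (T, C, Z, Y, X); singleton axes are
    allowed and common (a single two-channel z-stack has T=1).
    """

    data: np.ndarray
    pixel_size_nm: float
    z_step_um: float = 0.0
    time_interval_s: float = 0.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must be 5D (T, C, Z, Y, X); got {self.data.ndim}D — "
                "use ImageStack.from_array(arr, axes=...) to expand"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be >= 0")
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel axis")

    @classmethod
    def from_array(cls, arr: np.ndarray, axes: str, **meta) -> "ImageStack":
        """Build a stack from an array whose axis order is given by ``axes``.

        ``axes`` is a string over 'TCZYX' (e.g. ``"CZYX"``); missing axes
        become singletons.
        """
        arr = np.asarray(arr)
        axes = axes.upper()
        if arr.ndim != len(axes):
            raise ValueError(f"array has {arr.ndim} axes but axes string is {axes!r}")
        if len(set(axes)) != len(axes) or not set(axes) <= set(AXES):
            raise ValueError(f"axes must be unique letters from {AXES}, got {axes!r}")
        # move present axes into canonical order, then insert singletons
        order = [axes.index(a) for a in AXES if a in axes]
        arr = arr.transpose(order)
        for i, a in enumerate(AXES):
            if a not in axes:
                arr = np.expand_dims(arr, i)
        return cls(arr, **meta)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_zplanes(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def metadata(self) -> dict:
        return {
            "axes": AXES,
            "pixel_size_nm": self.pixel_size_nm,
            "z_step_um": self.z_step_um,
            "time_interval_s": self.time_interval_s,
            "channel_names": list(self.channel_names),
        }


@dataclass
class ProjectedImage:
    """Per-channel 2D rasters obtained by projecting a stack along z."""

    data: np.ndarray  # (C, Y, X)
    projection_mode: str
    pixel_size_nm: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ProjectedImage data must be (C, Y, X)")

    def channel(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.channel_names.index(key)
        return self.data[key]


# ---------------------------------------------------------------------------
# TIFF I/O.  Calibration travels in a JSON sidecar (and is also embedded in
# the TIFF description tag); the sidecar is authoritative on read.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, metadata={"axes": AXES})
    meta = stack.metadata()
    meta["dtype"] = str(stack.data.dtype)
    meta["shape"] = list(stack.data.shape)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | Path,
    axes: str | None = None,
    pixel_size_nm: float | None = None,
    z_step_um: float | None = None,
    time_interval_s: float | None = None,
) -> ImageStack:
    """Read a TIFF stack, resolving axis order and calibration.

    Resolution order: explicit overrides > JSON sidecar > TIFF series
    metadata.  Missing pixel size or ambiguous axes raise, never guess.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        file_axes = series.axes.upper().replace("S", "C").replace("Q", "")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    resolved_axes = axes or meta.get("axes")
    if resolved_axes is None:
        if set(file_axes) <= set(AXES) and len(file_axes) == arr.ndim:
            resolved_axes = file_axes
        else:
            raise ValueError(
                f"cannot resolve axis order for {path} (file reports {file_axes!r}); "
                "pass axes='...' explicitly"
            )
    if len(resolved_axes) > arr.ndim:
        # sidecar written for the full 5D shape; squeeze bookkeeping
        resolved_axes = resolved_axes[-arr.ndim:] if arr.ndim else resolved_axes
        arr = arr.reshape(meta["shape"]) if "shape" in meta else arr
        resolved_axes = meta.get("axes", resolved_axes)

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(
            f"pixel_size_nm missing for {path}: no sidecar value and no override given"
        )
    return ImageStack.from_array(
        arr.reshape(meta["shape"]) if "shape" in meta else arr,
        axes=meta.get("axes", resolved_axes) if "shape" in meta else resolved_axes,
        pixel_size_nm=px,
        z_step_um=z_step_um if z_step_um is not None else meta.get("z_step_um", 0.0),
        time_interval_s=(
            time_interval_s
            if time_interval_s is not None
            else meta.get("time_interval_s", 0.0)
        ),
        channel_names=meta.get("channel_names", []),
    )


# ---------------------------------------------------------------------------
# z-projection
# ---------------------------------------------------------------------------


def project(stack: ImageStack, mode: str = "average", timepoint: int = 0) -> ProjectedImage:
    """Project one timepoint of a stack along z (pixelwise mean or max)."""
    if mode not in ("average", "maximum"):
        raise ValueError(f"unknown projection mode {mode!r}")
    frame = stack.data[timepoint]  # (C, Z, Y, X)
    proj = frame.mean(axis=1) if mode == "average" else frame.max(axis=1)
    return ProjectedImage(
        data=proj,
        projection_mode=mode,
        pixel_size_nm=stack.pixel_size_nm,
        channel_names=list(stack.channel_names),
    )


# ---------------------------------------------------------------------------
# bleach correction
# ---------------------------------------------------------------------------


@dataclass
class BleachResult:
    stack: ImageStack
    mode: str
    frame_means: np.ndarray
    #: (a, k, c) of I(t) = a*exp(-k*t) + c fitted to frame means, or None
    fit_params: tuple[float, float, float] | None = None


def _exp_model(t, a, k, c):
    return a * np.exp(-k * t) + c


def bleach_correct(series: ImageStack, mode: str = "simple_ratio") -> BleachResult:
    """Correct intensity loss over a time series.

    ``simple_ratio`` rescales every frame so its mean equals the first
    frame's mean.  ``exponential_fit`` fits a*exp(-k*t)+c to the frame
    means and divides each frame by the fitted decay normalised to t=0;
    if the fit does not converge it falls back to simple_ratio with a
    warning.
    """
    if mode not in ("simple_ratio", "exponential_fit"):
        raise ValueError(f"unknown bleach-correction mode {mode!r}")
    n_t = series.n_timepoints
    if n_t < 3:
        raise ValueError(f"bleach correction needs >= 3 timepoints, got {n_t}")
    means = series.data.reshape(n_t, -1).mean(axis=1)
    if np.any(means <= 0):
        bad = int(np.argmax(means <= 0))
        raise ValueError(f"non-positive frame mean at timepoint {bad}")

    t = np.arange(n_t, dtype=float)
    if mode == "simple_ratio":
        scale = means[0] / means
        data = series.data * scale[:, None, None, None, None]
        return BleachResult(replace(series, data=data), mode, means)

    if np.ptp(means) / means.mean() < 1e-9:
        # constant series: nothing to correct, k is identically 0
        return BleachResult(
            replace(series, data=series.data.copy()),
            mode,
            means,
            fit_params=(0.0, 0.0, float(means[0])),
        )
    try:
        a0 = max(means[0] - means[-1], 1e-6 * means[0])
        k0 = max(-np.polyfit(t, np.log(np.maximum(means, 1e-12)), 1)[0], 1e-6)
        c0 = max(means[-1] - a0 * np.exp(-k0 * t[-1]), 0.0)
        popt, _ = curve_fit(
            _exp_model,
            t,
            means,
            p0=(a0, k0, c0),
            bounds=([0, 0, 0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        warnings.warn(
            "exponential bleach fit did not converge; falling back to simple_ratio",
            RuntimeWarning,
            stacklevel=2,
        )
        result = bleach_correct(series, mode="simple_ratio")
        return BleachResult(result.stack, "simple_ratio", means)
    a, k, c = popt
    decay = _exp_model(t, a, k, c) / _exp_model(0.0, a, k, c)
    data = series.data / decay[:, None, None, None, None]
    return BleachResult(
        replace(series, data=data), mode, means, fit_params=(float(a), float(k), float(c))
    )


# ---------------------------------------------------------------------------
# two-channel translation registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    #: displacement (dy, dx) of the moving image relative to the reference
    shift: np.ndarray
    #: moving image translated by -shift onto the reference frame
    aligned: np.ndarray
    #: False where the aligned raster was filled (edge pixels); these
    #: pixels must be excluded from downstream statistics
    valid_mask: np.ndarray


def register_channels(
    ref: np.ndarray,
    moving: np.ndarray,
    max_shift: float = 10.0,
    subpixel: bool = False,
    fill_value: float = 0.0,
) -> RegistrationResult:
    """Estimate and undo the translation between two camera channels.

    The shift is estimated by cross-correlation; the sign convention is
    that ``moving`` is displaced by ``+shift`` (dy, dx) relative to
    ``ref``.  Estimates beyond ``max_shift`` are clamped with a warning.
    """
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if ref.shape != moving.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {moving.shape}")
    if np.ptp(ref) == 0 or np.ptp(moving) == 0:
        raise ValueError("no registration signal: constant image")

    upsample = 20 if subpixel else 1
    detected, _, _ = phase_cross_correlation(
        ref, moving, upsample_factor=upsample, normalization=None
    )
    shift = -np.asarray(detected, dtype=float)  # displacement of moving wrt ref
    if np.any(np.abs(shift) > max_shift):
        warnings.warn(
            f"estimated shift {tuple(shift)} exceeds max_shift={max_shift}; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        shift = np.clip(shift, -max_shift, max_shift)

    if not subpixel:
        shift = np.round(shift)
        idy, idx = int(shift[0]), int(shift[1])
        aligned = np.roll(moving, (-idy, -idx), axis=(0, 1))
        valid = np.ones_like(aligned, dtype=bool)
        if idy > 0:
            valid[-idy:, :] = False
        elif idy < 0:
            valid[:-idy, :] = False
        if idx > 0:
            valid[:, -idx:] = False
        elif idx < 0:
            valid[:, :-idx] = False
    else:
        from scipy.ndimage import shift as nd_shift

        aligned = nd_shift(moving, -shift, order=1, mode="constant", cval=fill_value)
        valid = (
            nd_shift(np.ones_like(moving), -shift, order=1, mode="constant", cval=0.0)
            > 0.999
        )
    aligned = np.where(valid, aligned, fill_value)
    return RegistrationResult(shift=shift, aligned=aligned, valid_mask=valid)
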