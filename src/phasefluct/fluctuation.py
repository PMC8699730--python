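"""Spatio-temporal fluctuation analysis of OPD videos.

The pipeline converts a (T, H, W) OPD video of a single cell into one 2D
"fluctuation map": after masking out the cell edges and subtracting the
temporal mean frame, a 3D DFT is taken and, for every temporal frequency
omega in (0, Nyquist], the spatial power plane is radially averaged into
annular bins of spatial frequency q.  Rows are ordered by increasing omega,
columns by increasing q.  The map is the membrane-fluctuation power spectrum
of the cell and serves both as a stiffness-proxy summary and as the second
input modality of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

from .holography import OPDMap, OPDVideo

__all__ = [
    "CellMask",
    "TemporalStdMap",
    "FluctuationMap",
    "build_mask",
    "temporal_std_map",
    "fluctuation_map",
    "radial_average",
    "classifier_map",
]

MIN_MASK_PIXELS = 100


@dataclass
class CellMask:
    """Disk-shaped analysis region strictly inside the frame, away from cell edges."""

    pixels: np.ndarray
    center: tuple[float, float] | None = None
    radius_px: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        n_true = int(self.pixels.sum())
        if n_true < MIN_MASK_PIXELS:
            raise ValueError(
                f"mask selects only {n_true} pixels (minimum {MIN_MASK_PIXELS})")
        border = np.concatenate([self.pixels[0], self.pixels[-1],
                                 self.pixels[:, 0], self.pixels[:, -1]])
        if border.any():
            raise ValueError("mask touches the frame border")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class TemporalStdMap:
    """Per-pixel temporal standard deviation (nm); zero outside the mask."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("std map must be non-negative")


@dataclass
class FluctuationMap:
    """Radially averaged spatio-temporal PSD.

    ``power[i, j]`` is the mean squared spectral magnitude at temporal
    frequency ``omega_axis[i]`` (Hz) and spatial-frequency bin centered at
    ``q_axis[j]`` (cycles/pixel, or 1/um when a pixel size was supplied).
    """

    power: np.ndarray
    omega_axis: np.ndarray
    q_axis: np.ndarray
    q_unit: str = "cycles/pixel"

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.omega_axis = np.asarray(self.omega_axis, dtype=float)
        self.q_axis = np.asarray(self.q_axis, dtype=float)
        if self.power.shape != (self.omega_axis.size, self.q_axis.size):
            raise ValueError("power shape does not match axes")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        for ax in (self.omega_axis, self.q_axis):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("axes must be strictly increasing")


def build_mask(first_frame: OPDMap | np.ndarray, threshold_frac: float = 0.2,
               erode_frac: float = 0.7) -> CellMask:
    """Disk mask over the cell interior, built from the first video frame.

    The frame is thresholded at ``threshold_frac`` of its maximum; the mask is
    a disk at the thresholded region's centroid with radius ``erode_frac``
    times the region's equivalent radius sqrt(area/pi), shrunk if necessary to
    stay strictly inside the frame.  Eroding below the equivalent radius
    excludes the cell edge, where vibrations are elevated.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    if not 0 < erode_frac < 1:
        raise ValueError("erode_frac must be in (0, 1)")
    frame = first_frame.values if isinstance(first_frame, OPDMap) else np.asarray(first_frame, dtype=float)
    vmax = frame.max()
    support = frame > threshold_frac * vmax
    if vmax <= 0 or not support.any():
        raise ValueError("no cell detected in first frame")
    ys, xs = np.nonzero(support)
    cy, cx = float(ys.mean()), float(xs.mean())
    eq_radius = float(np.sqrt(support.sum() / np.pi))
    radius = erode_frac * eq_radius
    # keep the disk strictly off the outermost row/column
    h, w = frame.shape
    max_r = min(cy, cx, h - 1 - cy, w - 1 - cx) - 1.0
    radius = min(radius, max_r)
    if radius <= 0 or np.pi * radius ** 2 < MIN_MASK_PIXELS:
        raise ValueError("detected cell too small for a valid analysis disk")
    yy = np.arange(h)[:, None] - cy
    xx = np.arange(w)[None, :] - cx
    disk = yy ** 2 + xx ** 2 <= radius ** 2
    return CellMask(disk, center=(cy, cx), radius_px=radius)


def temporal_std_map(video: OPDVideo, mask: CellMask) -> TemporalStdMap:
    """Sample standard deviation over time per pixel, zeroed outside the mask."""
    frames = video.frames
    if frames.shape[1:] != mask.pixels.shape:
        raise ValueError("mask shape does not match video frames")
    std = frames.std(axis=0, ddof=1)
    std[~mask.pixels] = 0.0
    return TemporalStdMap(std)


def radial_average(power2d: np.ndarray, n_bins: int,
                   return_counts: bool = False):
    """Radially average a centered 2D spectral-power plane into annular bins.

    ``power2d`` must have its zero frequency at the array center (after
    fftshift).  Bin edges are equally spaced in radial DFT-index units from 0
    to the maximum (corner) radius, so every pixel falls in exactly one bin
    and the count-weighted bin means conserve the total.  Bins that contain
    no pixels are returned as NaN.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    power2d = np.asarray(power2d, dtype=float)
    h, w = power2d.shape
    yy = np.arange(h)[:, None] - h // 2
    xx = np.arange(w)[None, :] - w // 2
    r = np.hypot(yy, xx)
    r_max = r.max()
    if r_max == 0:
        idx = np.zeros_like(r, dtype=int)
    else:
        idx = np.minimum((r / r_max * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx.ravel(), minlength=n_bins).astype(float)
    sums = np.bincount(idx.ravel(), weights=power2d.ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if return_counts:
        return means, counts
    return means


def fluctuation_map(video: OPDVideo, mask: CellMask,
                    n_bins: int | None = None,
                    return_energy: bool = False):
    """Compute the radially averaged spatio-temporal PSD of a masked OPD video.

    Steps: zero outside the mask; subtract the time-average frame; 3D DFT over
    (t, y, x); squared magnitude; for each temporal frequency in (0, Nyquist]
    fold the conjugate-symmetric negative frequency in and radially average
    the spatial plane.  The omega = 0 plane is identically zero after mean
    subtraction and is excluded.  Power is reported per analyzed (masked)
    pixel so that maps from cells of different size are on a common scale.

    With ``return_energy=True`` also returns a dict carrying the total 3D
    spectral power, the masked mean-subtracted signal energy and the DFT
    size, for energy-bookkeeping (Parseval) checks.
    """
    frames = video.frames
    t, h, w = frames.shape
    if t < 4:
        raise ValueError("need at least 4 frames")
    if frames.shape[1:] != mask.pixels.shape:
        raise ValueError("mask shape does not match video frames")
    if n_bins is None:
        n_bins = min(h, w) // 2

    data = frames * mask.pixels[None, :, :]
    data = data - data.mean(axis=0, keepdims=True)
    spec = np.fft.fftn(data)
    power = np.abs(spec) ** 2
    # normalize per analyzed pixel: raw DFT power grows with the number of
    # masked pixels, which differs between cells; dividing by it makes maps
    # comparable across cells of different size
    norm = float(mask.pixels.sum())

    # Parseval bookkeeping: total spectral power == N * sum(signal^2)
    total_signal = float(np.sum(data ** 2))
    total_power = float(power.sum())
    n_total = data.size
    if total_signal > 0 and not np.isclose(total_power, n_total * total_signal,
                                           rtol=1e-6, atol=0.0):  # pragma: no cover
        raise AssertionError("Parseval check failed in fluctuation_map")

    # temporal frequencies 1 .. T//2 (positive side up to Nyquist); the
    # negative-frequency plane carries the mirrored spatial spectrum of a real
    # signal, so fold it in by averaging (keeps all rows on a common scale,
    # including the self-conjugate Nyquist row).
    n_omega = t // 2
    rows = []
    for i in range(1, n_omega + 1):
        plane = power[i]
        j = (t - i) % t
        if j != i:
            plane = 0.5 * (plane + power[j])
        rows.append(np.fft.fftshift(plane) / norm)

    profiles = np.stack([radial_average(p, n_bins) for p in rows])
    nonempty = ~np.all(np.isnan(profiles), axis=0)
    profiles = profiles[:, nonempty]

    omega = np.arange(1, n_omega + 1) * video.frame_rate_hz / t
    # bin centers in index units -> cycles/pixel (or 1/um with pixel size)
    yy = np.arange(h)[:, None] - h // 2
    xx = np.arange(w)[None, :] - w // 2
    r_max = float(np.hypot(yy, xx).max())
    centers_idx = (np.arange(n_bins) + 0.5) * r_max / n_bins
    q = centers_idx[nonempty] / ((h + w) / 2.0)
    unit = "cycles/pixel"
    if video.pixel_size_um is not None:
        q = q / video.pixel_size_um
        unit = "1/um"
    fmap = FluctuationMap(profiles, omega, q, q_unit=unit)
    if return_energy:
        return fmap, {"total_power": total_power,
                      "signal_energy": total_signal,
                      "n_total": n_total}
    return fmap


#: fixed log10-power display/classifier range (decades); covers PSDs from the
#: detection-noise floor to the low-frequency peak for nm-scale OPD videos.
LOG_POWER_RANGE = (-1.0, 9.0)


def log_scale_map(power: np.ndarray,
                  log_range: tuple[float, float] = LOG_POWER_RANGE) -> np.ndarray:
    """Map PSD values to [0, 1] on a fixed log10 scale.

    Unlike a per-map min-max, the fixed scale preserves absolute power-level
    differences between cells — which carry the stiffness contrast — while
    still compressing the many-decade dynamic range.  Values outside the
    range are clipped.
    """
    lo, hi = log_range
    power = np.maximum(np.asarray(power, dtype=float), 0.0)
    lg = np.log10(power + 10.0 ** lo)
    return np.clip((lg - lo) / (hi - lo), 0.0, 1.0)


def classifier_map(fmap: FluctuationMap, size: int | None = None) -> np.ndarray:
    """Render a fluctuation map as a [0, 1] image (display normalization).

    The PSD spans many decades, so it is log-compressed (log10(power + eps)
    with eps = 1e-12 of the map maximum) and min-max normalized to [0, 1];
    optionally resized (bilinear) to ``size x size``.  For classifier inputs
    use :func:`log_scale_map`, which keeps absolute levels comparable
    between cells.
    """
    p = fmap.power
    eps = 1e-12 * max(p.max(), np.finfo(float).tiny)
    img = np.log10(p + eps)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    if size is not None and img.shape != (size, size):
        img = transform.resize(img, (size, size), order=1, preserve_range=True,
                               anti_aliasing=size < min(img.shape), mode="reflect")
    return img
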