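"""Off-axis hologram reconstruction to optical path delay (OPD) maps.

An off-axis interferogram carries the complex sample field on a spatial
carrier.  The reconstruction isolates one cross-correlation lobe of the
hologram's 2D spectrum, recenters it, inverse-transforms, unwraps the phase
argument and converts phase to OPD in nanometres via OPD = phi * lambda / (2 pi).
A piston term (mean over a background region) is removed so that an empty
field of view maps to OPD = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import restoration, transform

__all__ = [
    "Hologram",
    "OPDMap",
    "OPDVideo",
    "CarrierOverlapError",
    "reconstruct_opd",
    "reconstruct_video",
    "unwrap_phase",
    "standardize_video",
]


class CarrierOverlapError(ValueError):
    """The requested crop region around the carrier lobe overlaps the DC term."""


@dataclass
class Hologram:
    """Single off-axis interferogram.

    Parameters
    ----------
    intensity
        2D non-negative camera image (arbitrary units).
    carrier_freq
        (f_y, f_x) spatial carrier in cycles/pixel; each |f| < 0.5.
    wavelength_nm
        Central illumination wavelength in nm.
    """

    intensity: np.ndarray
    carrier_freq: tuple[float, float]
    wavelength_nm: float

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")
        fy, fx = self.carrier_freq
        if np.hypot(fy, fx) <= 0:
            raise ValueError("carrier frequency magnitude must be > 0")
        if abs(fy) >= 0.5 or abs(fx) >= 0.5:
            raise ValueError("carrier frequency must be below Nyquist (|f| < 0.5)")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class OPDMap:
    """Optical-path-delay map in nm, optionally with object-plane pixel size."""

    values: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("OPD map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OPD map contains non-finite values")


@dataclass
class OPDVideo:
    """Stack of OPD frames (T, H, W) in nm with its acquisition rate in Hz."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float | None = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("OPD video must be a (T>=2, H, W) stack")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("OPD video contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """2D phase unwrapping.

    The output is congruent to the input modulo 2*pi at every pixel and is
    continuous wherever the underlying phase gradient stays below pi per
    pixel; it is defined only up to a global additive multiple of 2*pi.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if not np.all(np.isfinite(wrapped)):
        raise ValueError("wrapped phase contains non-finite values")
    return np.asarray(restoration.unwrap_phase(wrapped), dtype=float)


def _remove_piston(opd: np.ndarray, support_frac: float = 0.2) -> np.ndarray:
    """Subtract the background level (pixels outside the cell support).

    The background is the region below ``support_frac`` of the map's dynamic
    range; its median (robust to residual cell tails inside the region) is
    taken as the piston.
    """
    lo, hi = opd.min(), opd.max()
    rng = hi - lo
    if rng <= 0:
        return opd - opd.mean()
    background = opd - lo < support_frac * rng
    if not background.any():  # pragma: no cover - defensive
        background = np.ones_like(opd, dtype=bool)
    return opd - np.median(opd[background])


def reconstruct_opd(holo: Hologram, crop_radius: float | None = None) -> OPDMap:
    """Reconstruct an OPD map (nm) from one off-axis hologram.

    Parameters
    ----------
    holo
        The interferogram with carrier frequency and wavelength metadata.
    crop_radius
        Radius (cycles/pixel) of the disk cropped around the carrier lobe.
        Default: half the carrier-to-DC distance, capped at the margin to the
        Nyquist edge.  A radius reaching back to DC raises
        :class:`CarrierOverlapError`.
    """
    img = holo.intensity
    h, w = img.shape
    fy, fx = holo.carrier_freq
    f_mag = float(np.hypot(fy, fx))
    # distance (cycles/pixel) from the carrier to the nearest Nyquist edge
    margin = min(0.5 - abs(fy), 0.5 - abs(fx))
    if crop_radius is None:
        crop_radius = min(f_mag / 2.0, margin)
    if crop_radius <= 0:
        raise ValueError("crop radius must be positive")
    if crop_radius >= f_mag:
        raise CarrierOverlapError(
            f"crop radius {crop_radius:.4f} cycles/pixel reaches the DC term "
            f"(carrier magnitude {f_mag:.4f}); increase the carrier or shrink the crop"
        )

    spec = np.fft.fftshift(np.fft.fft2(img))
    cy, cx = h // 2, w // 2
    # carrier lobe center in (fftshifted) index coordinates
    py = cy + int(round(fy * h))
    px = cx + int(round(fx * w))
    yy = np.arange(h)[:, None] - py
    xx = np.arange(w)[None, :] - px
    # per-axis index radii corresponding to crop_radius cycles/pixel
    ry = max(crop_radius * h, 1.0)
    rx = max(crop_radius * w, 1.0)
    lobe = (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0

    recentered = np.zeros_like(spec)
    ys, xs = np.nonzero(lobe)
    ys_c = ys - py + cy
    xs_c = xs - px + cx
    keep = (ys_c >= 0) & (ys_c < h) & (xs_c >= 0) & (xs_c < w)
    recentered[ys_c[keep], xs_c[keep]] = spec[ys[keep], xs[keep]]

    field_c = np.fft.ifft2(np.fft.ifftshift(recentered))
    phase = unwrap_phase(np.angle(field_c))
    opd = phase * holo.wavelength_nm / (2.0 * np.pi)
    return OPDMap(_remove_piston(opd))


def reconstruct_video(holos: np.ndarray, carrier_freq: tuple[float, float],
                      wavelength_nm: float, frame_rate_hz: float,
                      crop_radius: float | None = None) -> OPDVideo:
    """Reconstruct a (T, H, W) hologram stack frame by frame."""
    frames = [
        reconstruct_opd(Hologram(f, carrier_freq, wavelength_nm), crop_radius).values
        for f in np.asarray(holos, dtype=float)
    ]
    return OPDVideo(np.stack(frames), frame_rate_hz)


def standardize_video(video: OPDVideo, size: int = 250) -> OPDVideo:
    """Resize every frame to ``size x size`` (bilinear, anti-aliased on downscale).

    Units (nm) and frame count are preserved; a constant frame stays constant.
    """
    if size < 2:
        raise ValueError("target size must be >= 2")
    t, h, w = video.frames.shape
    if h == size and w == size:
        return video
    anti_alias = size < min(h, w)
    out = np.empty((t, size, size), dtype=float)
    for i in range(t):
        out[i] = transform.resize(video.frames[i], (size, size), order=1,
                                  anti_aliasing=anti_alias, preserve_range=True,
                                  mode="reflect")
    scale = None
    if video.pixel_size_um is not None:
        scale = video.pixel_size_um * ((h / size) + (w / size)) / 2.0
    return OPDVideo(out, video.frame_rate_hz, pixel_size_um=scale)
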