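"""Synthetic single-cell OPD videos with class-dependent fluctuation statistics.

Stands in for recordings of live primary (SW480-like) and metastatic
(SW620-like) colorectal cancer cells: a static dome-shaped optical-thickness
profile plus a stationary colored Gaussian fluctuation field whose power
follows q^-a * omega^-b, with elevated amplitude in the outer cell-edge
annulus and additive white detection noise.  Metastatic cells are modelled as
softer: larger fluctuation amplitude and shallower spectral slopes, on a
smaller, slightly taller dome.

All randomness flows from the ``seed`` fields; the same seed reproduces a
bitwise-identical video.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .fluctuation import CellMask, FluctuationMap
from .holography import Hologram, OPDMap, OPDVideo

__all__ = [
    "SyntheticCellParams",
    "CLASS_DEFAULTS",
    "simulate_cell_video",
    "simulate_hologram",
    "sample_cell_params",
    "generate_dataset",
    "fit_spatial_exponent",
]

#: fraction of the dome radius considered cell interior; the annulus between
#: INTERIOR_FRAC and 1 is the "edge" region with boosted vibrations.
INTERIOR_FRAC = 0.8


@dataclass
class SyntheticCellParams:
    """Generative parameters for one synthetic cell video.

    Amplitudes are nm RMS; exponents are the power-law slopes of the
    fluctuation power versus spatial frequency q and temporal frequency
    omega.  Defaults mimic a 4 s acquisition at 500 frames/s scaled down to a
    64x64, 256-frame stack for desk-scale computation.
    """

    class_label: str = "primary"
    size: int = 64
    frames: int = 256
    frame_rate_hz: float = 500.0
    dome_peak_nm: float = 300.0
    dome_radius_px: float = 20.0
    fluct_amp_nm: float = 3.0
    spatial_exponent: float = 2.0
    temporal_exponent: float = 1.0
    edge_boost: float = 2.0
    noise_floor_nm: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in ("primary", "metastatic"):
            raise ValueError("class_label must be 'primary' or 'metastatic'")
        if self.frames < 4:
            raise ValueError("need at least 4 frames")
        if min(self.fluct_amp_nm, self.noise_floor_nm, self.dome_peak_nm) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.edge_boost < 0:
            raise ValueError("edge_boost must be >= 0")
        if not 0 < self.dome_radius_px < self.size / 2 - 1:
            raise ValueError("dome must fit strictly inside the frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")


#: class-conditional distributions of the per-cell parameters (mean, sd).
#: Metastatic cells are softer: double RMS fluctuation amplitude (the
#: stiffness proxy) on a smaller, slightly taller dome.  The power-law
#: slopes are common to both classes with per-cell scatter; the class
#: contrast in the fluctuation map is carried by the amplitude, as a
#: stiffness difference would be.
CLASS_DEFAULTS = {
    "primary": dict(dome_radius=(19.5, 2.75), dome_peak=(300.0, 30.0),
                    log_amp=(np.log(3.0), 0.3), spatial_exp=(2.0, 0.1),
                    temporal_exp=(1.0, 0.1)),
    "metastatic": dict(dome_radius=(15.5, 2.75), dome_peak=(330.0, 30.0),
                       log_amp=(np.log(6.0), 0.3), spatial_exp=(2.0, 0.1),
                       temporal_exp=(1.0, 0.1)),
}


def _dome(size: int, radius: float, peak: float) -> np.ndarray:
    yy = np.arange(size)[:, None] - size / 2.0
    xx = np.arange(size)[None, :] - size / 2.0
    r2 = (yy ** 2 + xx ** 2) / radius ** 2
    return peak * np.clip(1.0 - r2, 0.0, None)


def _colored_field(rng: np.random.Generator, t: int, h: int, w: int,
                   a: float, b: float) -> np.ndarray:
    """Zero-temporal-mean Gaussian field with power ~ q^-a * omega^-b."""
    noise = rng.standard_normal((t, h, w))
    ft = np.abs(np.fft.fftfreq(t)) * t
    fy = np.abs(np.fft.fftfreq(h)) * h
    fx = np.abs(np.fft.fftfreq(w)) * w
    q = np.hypot(fy[:, None], fx[None, :])
    amp_q = np.maximum(q, 1.0) ** (-a / 2.0)
    amp_t = np.maximum(ft, 1.0) ** (-b / 2.0)
    amp_t[0] = 0.0  # no static component; fluctuations are zero-mean in time
    filt = amp_t[:, None, None] * amp_q[None, :, :]
    field = np.fft.ifftn(np.fft.fftn(noise) * filt).real
    return field


def simulate_cell_video(params: SyntheticCellParams) -> tuple[OPDVideo, CellMask]:
    """Generate one cell video and its ground-truth interior analysis mask.

    The returned mask is the disk of radius ``INTERIOR_FRAC * dome_radius_px``
    at the dome center, i.e. the cell interior excluding the boosted edge
    annulus.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    size, t = p.size, p.frames
    dome = _dome(size, p.dome_radius_px, p.dome_peak_nm)

    yy = np.arange(size)[:, None] - size / 2.0
    xx = np.arange(size)[None, :] - size / 2.0
    r = np.hypot(yy, xx)
    interior = r <= INTERIOR_FRAC * p.dome_radius_px
    edge = (r > INTERIOR_FRAC * p.dome_radius_px) & (r <= p.dome_radius_px)

    if p.fluct_amp_nm > 0:
        field = _colored_field(rng, t, size, size,
                               p.spatial_exponent, p.temporal_exponent)
        rms = field[:, interior].std()
        field *= p.fluct_amp_nm / rms
        envelope = np.where(interior, 1.0, np.where(edge, p.edge_boost, 0.0))
        video = dome[None] + field * envelope[None]
    else:
        video = np.broadcast_to(dome, (t, size, size)).copy()
    if p.noise_floor_nm > 0:
        video = video + rng.normal(0.0, p.noise_floor_nm, (t, size, size))

    mask = CellMask(interior, center=(size / 2.0, size / 2.0),
                    radius_px=INTERIOR_FRAC * p.dome_radius_px)
    return OPDVideo(video, p.frame_rate_hz), mask


def simulate_hologram(opd: OPDMap, carrier_freq: tuple[float, float],
                      wavelength_nm: float = 633.0,
                      visibility: float = 0.9) -> Hologram:
    """Render an off-axis interferogram of an OPD map.

    intensity = 1 + visibility * cos(2 pi carrier . r + 2 pi OPD / lambda).
    Requires the sample phase gradient to stay below pi per pixel so the
    reconstruction's unwrapping precondition holds.
    """
    if not 0 < visibility <= 1:
        raise ValueError("visibility must be in (0, 1]")
    phase = 2.0 * np.pi * opd.values / wavelength_nm
    gy, gx = np.gradient(phase)
    if max(np.abs(gy).max(), np.abs(gx).max()) >= np.pi:
        raise ValueError("OPD phase gradient exceeds pi per pixel")
    h, w = opd.values.shape
    fy, fx = carrier_freq
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    intensity = 1.0 + visibility * np.cos(2.0 * np.pi * (fy * yy + fx * xx) + phase)
    return Hologram(intensity, carrier_freq, wavelength_nm)


def sample_cell_params(class_label: str, rng: np.random.Generator,
                       size: int = 64, frames: int = 256,
                       amp_scale: float = 1.0) -> SyntheticCellParams:
    """Draw per-cell parameters from the class-conditional distributions.

    ``amp_scale`` multiplies the class mean fluctuation amplitude (used to set
    the between-class amplitude ratio of a generated dataset).
    """
    d = CLASS_DEFAULTS[class_label]
    scale = size / 64.0
    # lower clip keeps the eroded analysis disk above the minimum mask area
    radius = float(np.clip(rng.normal(*d["dome_radius"]) * scale,
                           max(4.0, 0.16 * size), size / 2 - 2))
    peak = float(max(rng.normal(*d["dome_peak"]), 50.0))
    amp = float(np.exp(rng.normal(d["log_amp"][0], d["log_amp"][1]))) * amp_scale
    a = float(max(rng.normal(*d["spatial_exp"]), 0.5))
    b = float(max(rng.normal(*d["temporal_exp"]), 0.3))
    return SyntheticCellParams(
        class_label=class_label, size=size, frames=frames,
        dome_radius_px=radius, dome_peak_nm=peak, fluct_amp_nm=amp,
        spatial_exponent=a, temporal_exponent=b,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_dataset(n_per_class: int, seed: int = 0, size: int = 64,
                     frames: int = 256):
    """Yield ``(cell_id, params)`` for a balanced two-class dataset.

    Videos are not materialized here (a full dataset would be large);
    call :func:`simulate_cell_video` on each params object as needed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for label in ("primary", "metastatic"):
        for i in range(n_per_class):
            out.append((f"{label}_{i:03d}", sample_cell_params(label, rng,
                                                               size=size,
                                                               frames=frames)))
    return out


def fit_spatial_exponent(fmap: FluctuationMap, q_lo_frac: float = 0.06,
                         q_hi_frac: float = 0.5) -> float:
    """Estimate the spatial power-law exponent a of power ~ q^-a.

    Averages the map over temporal frequencies (the q-dependence is
    separable) and regresses log10(power) on log10(q) over the central range
    ``[q_lo_frac, q_hi_frac]`` cycles/pixel, avoiding the mask-limited lowest
    bins and the corner bins beyond Nyquist.
    """
    profile = np.nanmean(fmap.power, axis=0)
    q = fmap.q_axis
    sel = (q >= q_lo_frac) & (q <= q_hi_frac) & (profile > 0)
    if sel.sum() < 4:
        raise ValueError("too few q bins for a power-law fit")
    slope = sps.linregress(np.log10(q[sel]), np.log10(profile[sel])).slope
    return float(-slope)
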