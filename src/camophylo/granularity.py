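"""Multi-scale pattern-energy ("granularity") analysis.

A masked region's luminance pattern — the per-pixel mean of the red and
green reflectance channels — is decomposed into annular spatial-frequency
bands.  The default bank has 15 bands centered on wavelengths from 2 to
256 px in sqrt(2) steps.  Energy in a band is the sum of squared Fourier
amplitudes whose wavelength falls inside the band, normalized so that the
energies over all bands plus the out-of-bank residual reproduce the
mean-centered raster's variance exactly (Parseval).

Three descriptors summarize the spectrum:

* overall pattern contrast — total energy across all scales;
* dominant marking size    — the scale whose band holds the most energy;
* pattern diversity        — the dominant band's share of the total.

Images must be scanned at >= 15 px/mm; coarser rasters cannot resolve
the smallest bands and are excluded from pattern analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .colorimetry import ReflectanceImage

MIN_PX_PER_MM = 15.0


@dataclass(frozen=True)
class ScaleBank:
    """Geometric sequence of band-center wavelengths with band edges.

    ``band_edges_px`` has one more entry than ``scales_px``; band ``i``
    covers wavelengths ``[band_edges_px[i], band_edges_px[i+1])``.
    Interior edges sit at the geometric midpoint of adjacent scales.
    """

    scales_px: tuple[float, ...]
    band_edges_px: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.scales_px)
        if len(s) == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("scales must be positive and strictly increasing")
        if len(self.band_edges_px) != len(s) + 1:
            raise ValueError("need one more edge than scales")

    def __len__(self) -> int:
        return len(self.scales_px)

    def band(self, i: int) -> tuple[float, float]:
        return (self.band_edges_px[i], self.band_edges_px[i + 1])


@dataclass(frozen=True)
class GranularitySpectrum:
    """Band energies plus the three pattern descriptors.

    When the region is constant (zero total energy) the descriptors are
    NaN and ``undefined`` is True; such records are excluded downstream.
    """

    scales_px: tuple[float, ...]
    energy: tuple[float, ...]
    overall_contrast: float
    dominant_size_px: float
    diversity: float
    undefined: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "overall_contrast": self.overall_contrast,
            "dominant_size_px": self.dominant_size_px,
            "diversity": self.diversity,
        }


def build_scale_bank(
    min_px: float = 2.0, max_px: float = 256.0, ratio: float = math.sqrt(2.0)
) -> ScaleBank:
    """Geometric scale bank: min_px * ratio**k for k = 0, 1, ... up to max_px.

    The defaults give 15 scales, 2..256 px in sqrt(2) steps.
    """
    if not (0 < min_px <= max_px) or not ratio > 1:
        raise ValueError("require 0 < min_px <= max_px and ratio > 1")
    scales = [min_px]
    while scales[-1] * ratio <= max_px * (1 + 1e-9):
        scales.append(scales[-1] * ratio)
    edges = [min_px]
    edges += [math.sqrt(a * b) for a, b in zip(scales[:-1], scales[1:])]
    edges.append(scales[-1] * math.sqrt(ratio))
    return ScaleBank(tuple(scales), tuple(edges))


def pattern_channel(
    image: ReflectanceImage, mask_name: str
) -> tuple[np.ndarray, np.ndarray]:
    """Region luminance raster for pattern analysis.

    Per-pixel (R+G)/2 restricted to the mask's bounding box; pixels
    outside the mask are filled with the in-mask mean so they contribute
    no spurious band energy.  Returns (channel, mask) cropped alike.
    """
    m = image.mask(mask_name)
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    sub = image.pixels[sl]
    msub = m[sl]
    chan = 0.5 * (sub[..., 0] + sub[..., 1])
    fill = chan[msub].mean()
    out = np.where(msub, chan, fill)
    return out, msub


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def _wavelength_map(shape: tuple[int, int]) -> np.ndarray:
    """Wavelength (px/cycle) of every FFT bin; DC mapped to +inf."""
    h, w = shape
    fv = np.fft.fftfreq(h)[:, None]
    fu = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fv, fu)
    with np.errstate(divide="ignore"):
        return np.where(rho > 0, 1.0 / rho, np.inf)


def _spectral_power(channel: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Power per FFT bin (normalized to sum to the raster variance),
    the matching wavelength map, and the raster variance."""
    chan = np.asarray(channel, dtype=float)
    if chan.ndim != 2 or min(chan.shape) < 2:
        raise ValueError("pattern raster must be at least 2x2")
    centered = chan - chan.mean()
    var = float((centered**2).mean())
    ph, pw = _next_pow2(chan.shape[0]), _next_pow2(chan.shape[1])
    padded = np.zeros((ph, pw))
    padded[: chan.shape[0], : chan.shape[1]] = centered
    F = np.fft.fft2(padded)
    # |F|^2 / (padded count * original count): Parseval-exact against the
    # mean-centered original raster's variance.
    power = (F.real**2 + F.imag**2) / (padded.size * chan.size)
    return power, _wavelength_map(padded.shape), var


def band_energy(channel: np.ndarray, band: tuple[float, float]) -> float:
    """Pattern energy within a half-open wavelength band [lo, hi)."""
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid wavelength band {band}")
    if lo > min(channel.shape):
        raise ValueError(
            f"band {band} lies beyond representable wavelengths "
            f"for raster of shape {channel.shape}"
        )
    power, wl, _ = _spectral_power(channel)
    sel = (wl >= lo * (1 - 1e-12)) & (wl < hi)
    return float(power[sel].sum())


def granularity_spectrum(
    channel: np.ndarray,
    bank: ScaleBank | None = None,
    *,
    diversity: str = "of_total",
    energy: str = "power",
) -> GranularitySpectrum:
    """Band energies over the bank plus the three descriptors.

    diversity="of_total" (default) reports max(E)/sum(E); "of_rest"
    reports max(E)/(sum(E)-max(E)).  energy="sd" reports per-band
    standard deviations of the band-filtered raster (the square root of
    the spectral power) instead of power; descriptors follow the chosen
    scale.  Ties for the dominant band break toward the smallest scale.
    """
    if bank is None:
        bank = build_scale_bank()
    if diversity not in ("of_total", "of_rest"):
        raise ValueError(f"unknown diversity convention {diversity!r}")
    if energy not in ("power", "sd"):
        raise ValueError(f"unknown energy convention {energy!r}")
    power, wl, _ = _spectral_power(channel)
    energies = []
    for i in range(len(bank)):
        lo, hi = bank.band(i)
        sel = (wl >= lo * (1 - 1e-12)) & (wl < hi)
        energies.append(float(power[sel].sum()))
    e = np.asarray(energies)
    if energy == "sd":
        e = np.sqrt(e)
    total = float(e.sum())
    if total <= 0.0:
        return GranularitySpectrum(
            bank.scales_px, tuple(e), 0.0, math.nan, math.nan, undefined=True
        )
    imax = int(np.argmax(e))  # argmax takes the first (smallest) scale on ties
    emax = float(e[imax])
    div = emax / total if diversity == "of_total" else emax / (total - emax)
    return GranularitySpectrum(
        scales_px=bank.scales_px,
        energy=tuple(float(v) for v in e),
        overall_contrast=total,
        dominant_size_px=float(bank.scales_px[imax]),
        diversity=float(div),
    )


def check_pixel_scale(px_per_mm: float, threshold: float = MIN_PX_PER_MM) -> bool:
    """True when the raster is fine enough for pattern analysis (>= 15 px/mm)."""
    if not px_per_mm > 0:
        raise ValueError("px_per_mm must be positive")
    return px_per_mm >= threshold


def region_granularity(
    image: ReflectanceImage,
    mask_name: str,
    bank: ScaleBank | None = None,
    **kwargs,
) -> GranularitySpectrum:
    """Granularity spectrum of a masked region of a reflectance image."""
    chan, _ = pattern_channel(image, mask_name)
    return granularity_spectrum(chan, bank, **kwargs)
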