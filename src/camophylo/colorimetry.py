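"""Linear-reflectance calibration and opponent-channel color metrics.

Field photographs are normalized against the gray patches of a color
checker: each RGB channel is mapped to reflectance by a least-squares
straight line through the origin (linear sensor assumption, no dark
offset).  On the calibrated image, four region-level metrics are
computed from the mean RGB of a masked region:

* brightness  = (R + G + B) / 3             (achromatic intensity)
* saturation  = ||(1,1,1) - (R,G,B)||_2     (distance from pure white)
* hue1        = R / G                       (red-vs-green opponent ratio)
* hue2        = (R + G) / B                 (yellow-vs-blue opponent ratio)

Reflectance lives on a [0, 1] scale with "completely white" at (1,1,1),
so saturation is bounded by sqrt(3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class CalibrationError(ValueError):
    """Gray-standard set unusable for a linear fit."""


class MaskError(KeyError):
    """Named region mask missing or empty."""


@dataclass(frozen=True)
class GrayStandard:
    """One gray patch: its measured raw RGB means and its known reflectance."""

    measured_rgb: tuple[float, float, float]
    known_reflectance: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.measured_rgb)):
            raise CalibrationError("gray standard has non-finite measured values")
        if not 0.0 <= self.known_reflectance <= 1.0:
            raise CalibrationError(
                f"known reflectance {self.known_reflectance} outside [0, 1]"
            )


@dataclass
class ReflectanceImage:
    """Linear RGB reflectance raster with pixel scale and named region masks.

    Parameters
    ----------
    pixels : (H, W, 3) float array
        Per-channel linear reflectance in [0, 1].
    px_per_mm : float
        Spatial scale of the raster; must be positive.
    masks : mapping of str -> (H, W) bool array
        Named binary regions, typically ``"animal"`` and ``"background"``.
    """

    pixels: np.ndarray
    px_per_mm: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("reflectance values must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("reflectance values must lie in [0, 1]")
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")
        shape = self.pixels.shape[:2]
        self.masks = {k: np.asarray(m, dtype=bool) for k, m in self.masks.items()}
        for name, m in self.masks.items():
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != image {shape}")

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise MaskError(f"no mask named {name!r}; have {sorted(self.masks)}")
        m = self.masks[name]
        if not m.any():
            raise MaskError(f"mask {name!r} is empty")
        return m


@dataclass(frozen=True)
class ColorMetrics:
    brightness: float
    saturation: float
    hue1: float
    hue2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "brightness": self.brightness,
            "saturation": self.saturation,
            "hue1": self.hue1,
            "hue2": self.hue2,
        }


def fit_gray_calibration(standards: Sequence[GrayStandard]) -> np.ndarray:
    """Per-channel through-origin slopes mapping raw value -> reflectance.

    Minimizes sum_i (k_i - s * m_i)^2 per channel, giving
    s = sum(m k) / sum(m^2).
    """
    if len(standards) < 2:
        raise CalibrationError(
            f"need at least 2 gray standards, got {len(standards)}"
        )
    known = np.array([s.known_reflectance for s in standards], dtype=float)
    if np.any(np.diff(np.sort(known)) <= 0):
        raise CalibrationError("known reflectances must be strictly increasing")
    measured = np.array([s.measured_rgb for s in standards], dtype=float)  # (n, 3)
    denom = (measured**2).sum(axis=0)
    if np.any(denom <= 0) or np.all(measured == measured[0], axis=0).any():
        raise CalibrationError("degenerate gray standards: no variation in a channel")
    return (measured * known[:, None]).sum(axis=0) / denom


def calibrate_from_gray_standards(
    raw_image: np.ndarray,
    standards: Sequence[GrayStandard],
    *,
    px_per_mm: float = 1.0,
    masks: Mapping[str, np.ndarray] | None = None,
) -> ReflectanceImage:
    """Map a raw RGB raster to linear reflectance using gray standards.

    Out-of-gamut calibrated values are clipped to [0, 1]; the number of
    clipped pixels is recorded on the returned image as ``n_clipped``.
    """
    raw = np.asarray(raw_image, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise CalibrationError("raw image contains non-finite values")
    slopes = fit_gray_calibration(standards)
    cal = raw * slopes[None, None, :]
    n_clipped = int(np.count_nonzero((cal < 0.0) | (cal > 1.0)))
    img = ReflectanceImage(
        pixels=np.clip(cal, 0.0, 1.0),
        px_per_mm=px_per_mm,
        masks=dict(masks or {}),
    )
    img.n_clipped = n_clipped  # type: ignore[attr-defined]
    return img


def mean_region_reflectance(
    image: ReflectanceImage, mask_name: str
) -> tuple[float, float, float]:
    """Per-channel arithmetic mean reflectance over the named region."""
    m = image.mask(mask_name)
    means = image.pixels[m].mean(axis=0)
    return (float(means[0]), float(means[1]), float(means[2]))


def brightness(rgb: Sequence[float]) -> float:
    """Achromatic intensity: mean of the three channel values."""
    r, g, b = (float(v) for v in rgb)
    if not all(np.isfinite([r, g, b])):
        raise ValueError("RGB values must be finite")
    return (r + g + b) / 3.0


def saturation(rgb: Sequence[float]) -> float:
    """Euclidean distance from pure white (1,1,1); larger = more saturated."""
    arr = np.asarray(rgb, dtype=float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"RGB channels must lie in [0, 1], got {tuple(arr)}")
    return float(np.sqrt(((1.0 - arr) ** 2).sum()))


def hue1(rgb: Sequence[float]) -> float:
    """Red/green opponent ratio R/G; > 1 means redder than green."""
    r, g, _ = (float(v) for v in rgb)
    if g == 0.0:
        raise ZeroDivisionError("hue1 undefined when G = 0")
    return r / g


def hue2(rgb: Sequence[float]) -> float:
    """Yellow/blue opponent ratio (R+G)/B; large values mean more yellow."""
    r, g, b = (float(v) for v in rgb)
    if b == 0.0:
        raise ZeroDivisionError("hue2 undefined when B = 0")
    return (r + g) / b


def region_color_metrics(image: ReflectanceImage, mask_name: str) -> ColorMetrics:
    """All four color metrics computed on the region's mean RGB.

    Metrics are taken on the mean reflectance rather than averaged per
    pixel; this is stable under mask noise and matches region-level
    measurement of a dorsal surface.
    """
    rgb = mean_region_reflectance(image, mask_name)
    return ColorMetrics(
        brightness=brightness(rgb),
        saturation=saturation(rgb),
        hue1=hue1(rgb),
        hue2=hue2(rgb),
    )
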