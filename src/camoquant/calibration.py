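"""Pixel-to-reflectance calibration from in-image grey standards.

Photographs carry grey standards of known nominal reflectance; fitting the
pixel-value-versus-reflectance relation per channel linearises the (possibly
nonlinear) camera response so that region-of-interest measurements are on a
calibrated reflectance scale, insensitive to lighting fluctuations. With the
two standards of the study design the linear map is determined exactly; a
power-law model is available when three or more standards are present.

Also implements the midpoint-grey search used to construct acclimation
substrates: the printed grey level whose measured reflectance is closest to
the mean of the black and white paper reflectances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "ReflectanceStandard",
    "ChannelLinearisation",
    "RoiMeasurement",
    "DEFAULT_STANDARDS",
    "WHITE_BACKGROUND_STANDARDS",
    "standards_for_background",
    "fit_channel_linearisation",
    "calibrate_image",
    "measure_roi",
    "midpoint_grey_target",
]

#: Nominal reflectances (fractions) of the grey standards photographed with
#: every background type except white.
DEFAULT_STANDARDS = (0.0488, 0.4173)
#: Standards used for the white background, whose reflectance exceeds the
#: brighter default standard.
WHITE_BACKGROUND_STANDARDS = (0.4173, 0.9824)


def standards_for_background(background: str) -> tuple[float, float]:
    """Nominal standard pair photographed with a given background type.

    The white background carries the {41.73%, 98.24%} pair; every other
    background carries {4.88%, 41.73%}.
    """
    return WHITE_BACKGROUND_STANDARDS if background == "white" else DEFAULT_STANDARDS


@dataclass(frozen=True)
class Region:
    """Axis-aligned pixel box, 0-based with half-open intervals.

    Rows ``[top, bottom)`` and columns ``[left, right)``.
    """

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if self.bottom <= self.top or self.right <= self.left:
            raise ValueError(f"empty or inverted region: {self}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"negative region coordinates: {self}")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.bottom), slice(self.left, self.right))

    @property
    def n_pixels(self) -> int:
        return (self.bottom - self.top) * (self.right - self.left)


@dataclass(frozen=True)
class ReflectanceStandard:
    """A grey patch of known nominal reflectance at a known image location."""

    nominal_reflectance: float
    region: Region

    def __post_init__(self) -> None:
        if not 0 < self.nominal_reflectance <= 1:
            raise ValueError(
                f"nominal reflectance must be in (0, 1]; got {self.nominal_reflectance}"
            )


@dataclass
class RoiMeasurement:
    """Mean calibrated reflectance of a region of interest."""

    label: str
    mean_reflectance: np.ndarray  # one value per channel
    n_pixels: int


@dataclass
class ChannelLinearisation:
    """Per-channel pixel→reflectance map fitted to the in-image standards.

    ``model`` is ``"linear"`` (``R = gain * pixel + offset``) or ``"power"``
    (``R = gain * pixel**exponent + offset``); ``params`` holds one parameter
    row per channel. The fitted map must be strictly increasing over the
    observed pixel range.
    """

    model: str
    params: np.ndarray  # (n_channels, 2) linear / (n_channels, 3) power
    clip_range: tuple[float, float] = (0.0, 1.2)

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        """Map pixel values (H×W×C or per-channel vector) to reflectance.

        Calibrated values outside ``clip_range`` (noise can push flat patches
        past nominal) are clipped with a logged warning rather than erroring.
        """
        px = np.asarray(pixels, dtype=float)
        flat = px.reshape(-1, px.shape[-1]) if px.ndim > 1 else px.reshape(1, -1)
        if flat.shape[-1] != self.params.shape[0]:
            raise ValueError(
                f"expected {self.params.shape[0]} channels, got {flat.shape[-1]}"
            )
        out = np.empty_like(flat)
        for c in range(self.params.shape[0]):
            if self.model == "linear":
                gain, offset = self.params[c]
                out[:, c] = gain * flat[:, c] + offset
            else:
                gain, exponent, offset = self.params[c]
                out[:, c] = gain * np.power(np.clip(flat[:, c], 0, None), exponent) + offset
        lo, hi = self.clip_range
        n_out = int(((out < lo) | (out > hi)).sum())
        if n_out:
            logger.warning(
                "clipped %d calibrated values outside [%g, %g]", n_out, lo, hi
            )
            out = np.clip(out, lo, hi)
        return out.reshape(px.shape) if px.ndim > 1 else out.ravel()


def _patch_means(image: np.ndarray, region: Region) -> np.ndarray:
    """Per-channel mean pixel value of a patch."""
    if image.ndim == 2:
        image = image[:, :, None]
    h, w, _ = image.shape
    if region.bottom > h or region.right > w:
        raise ValueError(f"region {region} exceeds image bounds {(h, w)}")
    patch = image[region.slices()]
    return patch.reshape(-1, image.shape[2]).mean(axis=0)


def fit_channel_linearisation(
    image: np.ndarray,
    standards: Sequence[ReflectanceStandard],
    model: str = "linear",
) -> ChannelLinearisation:
    """Fit the pixel→reflectance map per channel from the grey standards.

    With exactly two standards the linear model is the exact two-point
    solution; with three or more, least squares. The power model
    (``R = a * pixel**g + b``) needs at least three standards. The fitted
    relation must be increasing: a decreasing pixel-versus-reflectance trend
    indicates mislabelled standards and raises.
    """
    if model not in ("linear", "power"):
        raise ValueError(f"unknown model {model!r}")
    if len(standards) < 2:
        raise ValueError("need at least 2 reflectance standards")
    nominals = np.array([s.nominal_reflectance for s in standards])
    if len(np.unique(nominals)) != len(nominals):
        raise ValueError("standard nominal reflectances must be distinct "
                         "(duplicates leave the linearisation underdetermined)")
    if model == "power" and len(standards) < 3:
        raise ValueError("power model requires >= 3 standards")

    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    n_channels = img.shape[2]
    means = np.stack([_patch_means(img, s.region) for s in standards])  # (k, C)

    order = np.argsort(nominals)
    nominals_sorted = nominals[order]
    params = []
    for c in range(n_channels):
        px = means[order, c]
        if np.any(np.diff(px) == 0):
            raise ValueError(
                f"channel {c}: identical standard pixel means; degenerate fit"
            )
        if np.any(np.diff(px) < 0):
            raise ValueError(
                f"channel {c}: pixel value decreases with reflectance; "
                "check standard labelling"
            )
        if model == "linear":
            gain, offset = np.polyfit(px, nominals_sorted, 1)
            if gain <= 0:
                raise ValueError(f"channel {c}: non-increasing linear fit")
            params.append((gain, offset))
        else:
            def powerlaw(p, a, g, b):
                return a * np.power(p, g) + b

            p0 = ((nominals_sorted[-1] - nominals_sorted[0])
                  / max(px[-1] - px[0], 1e-12), 1.0, nominals_sorted[0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(powerlaw, px, nominals_sorted, p0=p0,
                                    maxfev=20000)
            a, g, b = popt
            if a <= 0 or g <= 0:
                raise ValueError(f"channel {c}: non-increasing power fit")
            params.append((a, g, b))
    return ChannelLinearisation(model=model, params=np.array(params))


def calibrate_image(
    image: np.ndarray,
    standards: Sequence[ReflectanceStandard],
    model: str = "linear",
) -> tuple[np.ndarray, ChannelLinearisation]:
    """Fit the linearisation and return the calibrated reflectance image."""
    lin = fit_channel_linearisation(image, standards, model=model)
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    return lin.apply(img), lin


def measure_roi(calibrated: np.ndarray, region: Region, label: str = "roi") -> RoiMeasurement:
    """Arithmetic mean calibrated reflectance of a region of interest."""
    means = _patch_means(np.asarray(calibrated, dtype=float), region)
    return RoiMeasurement(label=label, mean_reflectance=means,
                          n_pixels=region.n_pixels)


def midpoint_grey_target(
    black_reflectance: float,
    white_reflectance: float,
    printer_curve: Sequence[float] | None = None,
) -> tuple[float, int | None]:
    """Target reflectance and printed grey level for an acclimation substrate.

    The target is the arithmetic mean of the black and white paper
    reflectances. If a printer response curve is given (measured reflectance
    for each of the 256 8-bit grey levels, monotone non-decreasing), the
    returned level is the one whose printed reflectance is nearest the
    target, ties resolved toward the lower level — the fixed point of the
    iterative print-photograph-refine search, found here in a single pass.
    """
    if not 0 < black_reflectance <= white_reflectance < 1:
        raise ValueError(
            "need 0 < black <= white < 1; got "
            f"{black_reflectance}, {white_reflectance}"
        )
    target = (black_reflectance + white_reflectance) / 2.0
    if printer_curve is None:
        return target, None
    curve = np.asarray(printer_curve, dtype=float)
    if curve.ndim != 1 or len(curve) != 256:
        raise ValueError("printer curve must give reflectance for 256 RGB levels")
    if np.any(np.diff(curve) < 0):
        raise ValueError("printer curve must be monotone non-decreasing")
    err = np.abs(curve - target)
    level = int(np.argmin(err))  # argmin takes the first (lowest) on ties
    return target, level
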