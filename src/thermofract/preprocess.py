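"""Contralateral normalization and magnitude-spectrum preprocessing.

Skin temperature varies between people, so the injured-wrist ROI is first
expressed relative to the mean temperature of the contralateral
(uninjured) wrist ROI.  The normalized ROI is then 2D-Fourier transformed;
the DC-centered magnitude spectrum is cropped to its central 100 x 100
window, which both resizes ROIs of differing dimensions to a common shape
and keeps the dominant low-frequency content.  An 8-bit grayscale PNG
rendering (log-scaled, per-image min-max) is provided for on-disk export.

Conventions (fixed, 0-based, row-major):
- ROIs narrower than 100 pixels in a dimension are zero-padded
  symmetrically before the transform (any odd leftover pixel goes after).
- The zero-frequency bin sits at index (floor(H/2), floor(W/2)) after the
  shift; the central crop spans rows [cH - 50, cH + 50) and likewise for
  columns, which places DC at (50, 50) of the cropped window.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import CohortDataset, Participant

TARGET_SHAPE = (100, 100)

__all__ = [
    "NormalizedROI",
    "SpectrumImage",
    "normalize_injured_roi",
    "pad_to_minimum",
    "full_magnitude_spectrum",
    "center_crop",
    "magnitude_spectrum",
    "spectrum_to_uint8",
    "to_png",
    "png_to_array",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class NormalizedROI:
    """Injured-wrist ROI in deg C relative to the contralateral mean."""

    pixels: np.ndarray
    participant_id: str = ""
    frame_index: int = 0


@dataclass(frozen=True)
class SpectrumImage:
    """100 x 100 DC-centered magnitude spectrum plus provenance."""

    magnitude: np.ndarray
    participant_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.magnitude.shape != TARGET_SHAPE:
            raise ValueError(f"magnitude must be {TARGET_SHAPE}, got {self.magnitude.shape}")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude spectrum must be non-negative")

    @property
    def png_pixels(self) -> np.ndarray:
        """8-bit rendering: round(255 * log1p(m) / max(log1p(m)))."""
        return spectrum_to_uint8(self.magnitude)


def normalize_injured_roi(
    injured: np.ndarray,
    uninjured: np.ndarray,
    participant_id: str = "",
    frame_index: int = 0,
) -> NormalizedROI:
    """Subtract the mean of the uninjured ROI from every injured-ROI pixel."""
    injured = np.asarray(injured, dtype=float)
    uninjured = np.asarray(uninjured, dtype=float)
    for name, arr in (("injured", injured), ("uninjured", uninjured)):
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"{name} ROI must be a non-empty 2D matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} ROI contains non-finite values")
    return NormalizedROI(injured - uninjured.mean(), participant_id, frame_index)


def pad_to_minimum(pixels: np.ndarray, min_shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Zero-pad symmetrically so each dim is at least the target size.

    Spatial zero-padding refines the frequency sampling of the DFT without
    altering image content (the spectrum of the padded image interpolates
    that of the original), so sub-100-pixel ROIs remain comparable.
    """
    h, w = pixels.shape
    pad_h = max(min_shape[0] - h, 0)
    pad_w = max(min_shape[1] - w, 0)
    if pad_h == 0 and pad_w == 0:
        return pixels
    return np.pad(pixels, ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)))


def full_magnitude_spectrum(pixels: np.ndarray) -> np.ndarray:
    """|2D DFT| with the zero-frequency bin shifted to (floor(H/2), floor(W/2))."""
    return np.abs(np.fft.fftshift(np.fft.fft2(pixels)))


def center_crop(spectrum: np.ndarray, target: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Half-open central window [c - t//2, c + t - t//2) around the DC bin."""
    h, w = spectrum.shape
    th, tw = target
    if th > h or tw > w:
        raise ValueError("crop target exceeds spectrum size")
    ch, cw = h // 2, w // 2
    return spectrum[ch - th // 2 : ch + th - th // 2, cw - tw // 2 : cw + tw - tw // 2]


def magnitude_spectrum(roi: NormalizedROI, target: tuple[int, int] = TARGET_SHAPE) -> SpectrumImage:
    """Normalized ROI -> DC-centered central magnitude window.

    The DC bin of the result equals |sum of the input pixels| because zero
    padding leaves the image sum unchanged.
    """
    pixels = np.asarray(roi.pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("ROI contains non-finite values")
    padded = pad_to_minimum(pixels, target)
    mag = center_crop(full_magnitude_spectrum(padded), target)
    return SpectrumImage(np.ascontiguousarray(mag), roi.participant_id, roi.frame_index)


def spectrum_to_uint8(magnitude: np.ndarray) -> np.ndarray:
    """Log-scale then min-max map to [0, 255]; all-zero input stays all zero.

    The DC bin can exceed the texture bins by orders of magnitude; without
    the log it would saturate the 8-bit range and flatten everything else.
    """
    s = np.log1p(np.asarray(magnitude, dtype=float))
    peak = s.max()
    if peak == 0:
        return np.zeros(s.shape, dtype=np.uint8)
    return np.rint(255.0 * s / peak).astype(np.uint8)


def to_png(spectrum: SpectrumImage) -> bytes:
    """Encode the 8-bit rendering as grayscale PNG bytes (lossless)."""
    buf = io.BytesIO()
    Image.fromarray(spectrum.png_pixels, mode="L").save(buf, format="PNG")
    return buf.getvalue()


def png_to_array(png_bytes: bytes) -> np.ndarray:
    """Decode grayscale PNG bytes back to a uint8 matrix."""
    with Image.open(io.BytesIO(png_bytes)) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def write_png(spectrum: SpectrumImage, path: str | Path) -> None:
    Path(path).write_bytes(to_png(spectrum))


def preprocess_cohort(cohort: CohortDataset, use_png_quantized: bool = False) -> CohortDataset:
    """Map every (injured, uninjured) frame pair to a SpectrumImage.

    Only injured-wrist spectra feed the classifier; the uninjured wrist
    contributes its mean as the per-participant baseline.  With
    ``use_png_quantized`` the float magnitudes are replaced by their 8-bit
    PNG rendering (strict fidelity to an on-disk PNG pathway); the default
    keeps full float precision.
    """
    out = []
    for p in cohort:
        spectra = []
        for injured, uninjured in p.items:
            roi = normalize_injured_roi(
                injured.pixels, uninjured.pixels, p.participant_id, injured.frame_index
            )
            spec = magnitude_spectrum(roi)
            if use_png_quantized:
                spec = SpectrumImage(
                    spec.png_pixels.astype(float), spec.participant_id, spec.frame_index
                )
            spectra.append(spec)
        out.append(Participant(p.participant_id, p.label, spectra))
    return CohortDataset(out, stage="spectrum")
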