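"""Seeded generators for the synthetic vision-science stimuli.

Each generator is a pure function of its config (seed included): the same
config always yields the bitwise-identical stimulus.

* :func:`make_onoff_stimulus` — 1D alternating black/white bars with a
  superimposed gray center segment (ON/OFF polarity-reversal experiment).
* :func:`make_brightness_display` — the 11-circle brightness-scaling
  display on a uniform or salt-and-pepper background, in cd/m^2
  (crispening experiment).
* :func:`make_white_stimulus` / :func:`add_bandpass_noise` — White's
  illusion grating with two equal-gray test patches and isotropic
  one-octave bandpass noise.
* :func:`make_irradiation_signal` — the 1D step figure of the irradiation
  illusion, in both polarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

from .core import Raster

__all__ = [
    "DISPLAY_BLACK",
    "DISPLAY_WHITE",
    "OnOffConfig",
    "BrightnessDisplayConfig",
    "WhiteStimulusConfig",
    "make_onoff_stimulus",
    "make_brightness_display",
    "display_circle_centers",
    "make_white_stimulus",
    "white_patch_masks",
    "add_bandpass_noise",
    "make_irradiation_signal",
]

#: Calibrated display black and white, cd/m^2.
DISPLAY_BLACK = 0.65
DISPLAY_WHITE = 75.0


# ---------------------------------------------------------------------------
# ON/OFF bar stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnOffConfig:
    """1D bar stimulus: square-wave background with a gray center segment."""

    total_width: int = 512
    center_width: int = 64
    bar_width: int = 128
    center_value: float = 0.5
    blur_sigma: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.center_value <= 1):
            raise ValueError("center_value must lie in [0, 1]")
        if self.center_width >= self.total_width:
            raise ValueError("center_width must be smaller than total_width")
        if self.bar_width >= self.total_width // 2:
            raise ValueError("bar_width >= half the signal gives a degenerate background")


def make_onoff_stimulus(cfg: OnOffConfig) -> Raster:
    """Square wave of period ``2*bar_width`` (white bar first) with the
    central ``center_width`` samples replaced by ``center_value``.

    No blur is applied here; ``cfg.blur_sigma`` travels as metadata for the
    experiment pipeline.
    """
    n = cfg.total_width
    idx = np.arange(n)
    signal = np.where((idx // cfg.bar_width) % 2 == 0, 1.0, 0.0)
    start = (n - cfg.center_width) // 2
    signal[start:start + cfg.center_width] = cfg.center_value
    return Raster(signal, value_range=(0.0, 1.0))


# ---------------------------------------------------------------------------
# Brightness-scaling display
# ---------------------------------------------------------------------------

def _default_circle_luminances() -> Tuple[float, ...]:
    return tuple(np.linspace(DISPLAY_BLACK, DISPLAY_WHITE, 11))


@dataclass(frozen=True)
class BrightnessDisplayConfig:
    """Eleven circles on the horizontal meridian of a calibrated display.

    The printed display is 1280x960 px at 64 px/deg with 1-degree (64 px)
    circles.  Eleven 64 px circles with 64 px gaps would span 1344 px and
    not fit the canvas, so the default gap is the largest integer gap that
    does (57 px), keeping the printed canvas and circle size.
    """

    background_kind: Literal["uniform", "salt_pepper"] = "uniform"
    background_level: float = 37.83  # cd/m^2 (uniform) or black fraction (salt_pepper)
    circle_luminances: Tuple[float, ...] = field(default_factory=_default_circle_luminances)
    circle_diameter_px: int = 64
    gap_px: int = 57
    canvas: Tuple[int, int] = (960, 1280)  # rows, cols
    pixels_per_degree: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.circle_luminances) != 11:
            raise ValueError("exactly 11 circles are required")
        for L in self.circle_luminances:
            if not (DISPLAY_BLACK <= L <= DISPLAY_WHITE):
                raise ValueError("circle luminance outside the display range")
        if self.background_kind == "uniform":
            if not (DISPLAY_BLACK <= self.background_level <= DISPLAY_WHITE):
                raise ValueError("uniform background level outside the display range")
        elif self.background_kind == "salt_pepper":
            if not (0.0 <= self.background_level <= 1.0):
                raise ValueError("salt-pepper black fraction must lie in [0, 1]")
        else:
            raise ValueError(f"unknown background kind {self.background_kind!r}")


def display_circle_centers(cfg: BrightnessDisplayConfig) -> list[Tuple[int, int]]:
    """(row, col) centers of the 11 circles, left to right."""
    h, w = cfg.canvas
    d, gap = cfg.circle_diameter_px, cfg.gap_px
    span = 11 * d + 10 * gap
    if span > w or d > h:
        raise ValueError("circle layout does not fit the canvas")
    margin = (w - span) // 2
    row = h // 2
    return [(row, margin + d // 2 + i * (d + gap)) for i in range(11)]


def make_brightness_display(cfg: BrightnessDisplayConfig) -> Raster:
    """Render the display in luminance (cd/m^2).

    Salt-and-pepper backgrounds draw each pixel independently: black
    (0.65 cd/m^2) with probability ``background_level``, else white
    (75 cd/m^2), from a generator seeded by ``cfg.seed``.
    """
    h, w = cfg.canvas
    if cfg.background_kind == "uniform":
        img = np.full((h, w), float(cfg.background_level))
    else:
        rng = np.random.default_rng(cfg.seed)
        black = rng.random((h, w)) < cfg.background_level
        img = np.where(black, DISPLAY_BLACK, DISPLAY_WHITE)
    centers = display_circle_centers(cfg)
    r = cfg.circle_diameter_px / 2.0
    rows, cols = np.ogrid[:h, :w]
    for (rc, cc), L in zip(centers, cfg.circle_luminances):
        mask = (rows - rc) ** 2 + (cols - cc) ** 2 < r * r
        img[mask] = L
    return Raster(img, value_range=(DISPLAY_BLACK, DISPLAY_WHITE),
                  pixels_per_degree=cfg.pixels_per_degree)


# ---------------------------------------------------------------------------
# White's illusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WhiteStimulusConfig:
    """Square-wave grating with two equal-gray test patches.

    Vertical bars of ``bar_width_px`` alternate white (even bars) and
    black.  Both patches have the same gray value; one sits on a white
    bar, the other on a black bar, each one bar wide and
    ``patch_height_px`` tall, centered vertically.
    """

    canvas: Tuple[int, int] = (384, 384)
    bar_width_px: int = 64
    test_gray: float = 0.5
    patch_height_px: int = 128
    patch_bars: Tuple[int, int] = (2, 5)  # (white-bar index, black-bar index)
    pixels_per_degree: float = 64.0
    noise_center_cpd: float = 0.0  # 0 = no noise
    noise_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas
        if not (0.0 <= self.test_gray <= 1.0):
            raise ValueError("test_gray must lie in [0, 1]")
        if self.patch_height_px > h:
            raise ValueError("test patch taller than the canvas")
        wb, bb = self.patch_bars
        if wb % 2 != 0 or bb % 2 != 1:
            raise ValueError("patch_bars must be (even white-bar, odd black-bar) indices")
        for b in self.patch_bars:
            if (b + 1) * self.bar_width_px > w:
                raise ValueError("test patch outside the canvas")


def white_patch_masks(cfg: WhiteStimulusConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean masks (on-white-bar patch, on-black-bar patch)."""
    h, w = cfg.canvas
    top = (h - cfg.patch_height_px) // 2
    rows = slice(top, top + cfg.patch_height_px)
    masks = []
    for b in cfg.patch_bars:
        m = np.zeros((h, w), dtype=bool)
        m[rows, b * cfg.bar_width_px:(b + 1) * cfg.bar_width_px] = True
        masks.append(m)
    return masks[0], masks[1]


def make_white_stimulus(cfg: WhiteStimulusConfig) -> Raster:
    """Render the grating, place the patches, optionally add bandpass noise."""
    h, w = cfg.canvas
    cols = np.arange(w)
    img = np.where((cols // cfg.bar_width_px) % 2 == 0, 1.0, 0.0)
    img = np.broadcast_to(img, (h, w)).copy()
    for mask in white_patch_masks(cfg):
        img[mask] = cfg.test_gray
    stim = Raster(img, value_range=(0.0, 1.0), pixels_per_degree=cfg.pixels_per_degree)
    if cfg.noise_rms > 0 and cfg.noise_center_cpd > 0:
        stim = add_bandpass_noise(stim, cfg.noise_center_cpd, cfg.noise_rms, cfg.seed)
    return stim


def add_bandpass_noise(I: Raster, center_freq_cpd: float, rms: float,
                       seed: int = 0) -> Raster:
    """Add zero-mean isotropic bandpass Gaussian noise to a 2D raster.

    White Gaussian noise is filtered in the frequency domain by an annulus
    of one octave full width centered at ``center_freq_cpd`` (band edges at
    ``f0/sqrt(2)`` and ``f0*sqrt(2)``), then rescaled to the requested rms
    and added.  Requires ``pixels_per_degree`` metadata on the raster.
    """
    if not isinstance(I, Raster) or I.pixels_per_degree is None:
        raise ValueError("bandpass noise requires a Raster with pixels_per_degree")
    if I.values.ndim != 2:
        raise ValueError("bandpass noise is defined for 2D rasters")
    if rms < 0:
        raise ValueError("rms must be nonnegative")
    if rms == 0:
        return I.with_values(I.values.copy())
    h, w = I.values.shape
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h, d=1.0 / I.pixels_per_degree)
    fx = np.fft.fftfreq(w, d=1.0 / I.pixels_per_degree)
    f = np.hypot(fy[:, None], fx[None, :])
    band = (f >= center_freq_cpd / np.sqrt(2)) & (f <= center_freq_cpd * np.sqrt(2))
    if not band.any():
        raise ValueError("noise band is empty at this resolution")
    filtered = np.fft.ifft2(np.fft.fft2(noise) * band).real
    filtered -= filtered.mean()
    filtered *= rms / np.sqrt(np.mean(filtered ** 2))
    return I.with_values(I.values + filtered)


# ---------------------------------------------------------------------------
# Irradiation step
# ---------------------------------------------------------------------------

def make_irradiation_signal(
    polarity: Literal["white_on_black", "black_on_white"] = "white_on_black",
    total_width: int = 1024,
    step_width: int = 400,
) -> Raster:
    """1D binary step figure: a central segment on the opposite ground."""
    if polarity not in ("white_on_black", "black_on_white"):
        raise ValueError(f"unknown polarity {polarity!r}")
    signal = np.zeros(total_width)
    start = (total_width - step_width) // 2
    signal[start:start + step_width] = 1.0
    if polarity == "black_on_white":
        signal = 1.0 - signal
    return Raster(signal, value_range=(0.0, 1.0))
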