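"""Pre-INRF signal transforms.

The vision-science pipelines precede the INRF stage with a small front end
that emulates early visual processing: optical/retinal blur (a Gaussian),
photoreceptor compression (a Naka–Rushton saturating response), the CIELAB
lightness transform (which plays the photoreceptor role for the image
quality metric), or a plain power law for gamma-corrected data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from skimage import color

from .core import Boundary, Raster, _conv_spec, _like, _values
from .primitives import KernelSpec

__all__ = [
    "PhotoreceptorSpec",
    "naka_rushton",
    "crispening_semisaturation",
    "srgb_to_lightness",
    "power_law",
    "retinal_blur",
    "apply_photoreceptor",
]


@dataclass(frozen=True)
class PhotoreceptorSpec:
    """Which photoreceptor-stage transform a pipeline uses.

    ``naka_rushton`` uses fixed exponent ``n`` and semisaturation ``S``;
    ``naka_rushton_adaptive`` derives ``S`` from the stimulus mean
    luminance via :func:`crispening_semisaturation`; ``cielab_lightness``
    takes L* of an sRGB image; ``power_law`` raises the (gamma-corrected)
    signal to ``gamma``; ``none`` is the identity.
    """

    kind: Literal["naka_rushton", "naka_rushton_adaptive", "cielab_lightness",
                  "power_law", "none"] = "none"
    n: float = 0.74
    S: Optional[float] = None
    gamma: float = 2.2

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("Naka-Rushton exponent n must be positive")
        if self.S is not None and self.S <= 0:
            raise ValueError("semisaturation S must be positive")


def naka_rushton(L, S: float, n: float = 1.0):
    """Saturating photoreceptor response ``L**n / (L**n + S**n)``.

    Maps nonnegative luminance into [0, 1): 0 at 0, exactly 0.5 at
    ``L = S`` for any exponent.  The irradiation pipeline uses the special
    case ``NR(v) = v/(v + 0.18)`` (``n = 1``, mid-gray semisaturation).
    """
    if S <= 0:
        raise ValueError("semisaturation S must be positive")
    if n <= 0:
        raise ValueError("exponent n must be positive")
    x = _values(L)
    if np.any(x < 0):
        raise ValueError("luminance must be nonnegative")
    xn = x ** n
    return _like(L, xn / (xn + S ** n))


def crispening_semisaturation(b_k: float) -> float:
    """Semisaturation constant adapted to the mean luminance ``b_k``.

    ``S = 0.5*18 + 0.5*10**(0.63*log10(b_k) + 1)`` — an empirical
    luminance-adaptation rule: half a fixed mid-gray term, half a term
    growing as a power of the adapting (mean) luminance in cd/m^2.
    """
    if b_k <= 0:
        raise ValueError("mean luminance must be positive")
    return 0.5 * 18.0 + 0.5 * 10.0 ** (0.63 * np.log10(b_k) + 1.0)


def srgb_to_lightness(img) -> np.ndarray:
    """CIELAB L* (D65 2-degree white) of an 8-bit sRGB image, in [0, 100]."""
    arr = img.values if isinstance(img, Raster) else np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 sRGB image")
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    return color.rgb2lab(arr)[..., 0]


def power_law(I, gamma: float = 2.2):
    """Elementwise ``I**gamma`` for nonnegative gamma-corrected data."""
    x = _values(I)
    if np.any(x < 0):
        raise ValueError("power law input must be nonnegative")
    return _like(I, x ** gamma)


def retinal_blur(I, sigma_px: float, boundary: Boundary = "mirror"):
    """Gaussian blur emulating retinal/optical spread; sigma 0 = identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be nonnegative")
    if sigma_px == 0:
        return _like(I, _values(I).copy())
    spec = KernelSpec(kind="gaussian", sigma_px=float(sigma_px))
    return _like(I, _conv_spec(_values(I), spec, boundary))


def apply_photoreceptor(I, spec: PhotoreceptorSpec):
    """Dispatch a :class:`PhotoreceptorSpec` over a luminance raster."""
    if spec.kind == "none":
        return _like(I, _values(I).copy())
    if spec.kind == "power_law":
        return power_law(I, spec.gamma)
    if spec.kind == "naka_rushton":
        if spec.S is None:
            raise ValueError("naka_rushton requires S")
        return naka_rushton(I, spec.S, spec.n)
    if spec.kind == "naka_rushton_adaptive":
        S = crispening_semisaturation(float(np.mean(_values(I))))
        return naka_rushton(I, S, spec.n)
    if spec.kind == "cielab_lightness":
        return srgb_to_lightness(I)
    raise ValueError(f"unknown photoreceptor kind {spec.kind!r}")
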