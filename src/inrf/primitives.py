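"""Declarative kernels and pointwise nonlinearities.

Every model in this package is assembled from two small vocabularies:

* :class:`KernelSpec` — the spatial summation kernels (the linear weights
  ``m``, the nonlinear-branch weights ``w`` and the local-mean kernel ``g``
  of the INRF operator, plus the DoG used by the linear-nonlinear baseline);
* :class:`NonlinearitySpec` — the pointwise nonlinearity ``sigma`` applied
  to centered intensity differences.

Specs are plain declarative dataclasses; :func:`realize_kernel` turns a spec
into a centered, odd-extent numpy grid and :func:`eval_sigma` evaluates a
nonlinearity elementwise.  Both are deterministic pure functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, Tuple, Union

import numpy as np

__all__ = [
    "InvalidSpecError",
    "KernelSpec",
    "NonlinearitySpec",
    "realize_kernel",
    "gaussian_taps",
    "eval_sigma",
]

logger = logging.getLogger("inrf")

KernelKind = Literal["delta", "box", "gaussian", "dog", "constant_full"]
SigmaKind = Literal["asymmetric_power", "piecewise_sinusoid", "scaled_identity", "sign"]

#: Gaussian support is truncated at +/- this many standard deviations and the
#: kernel renormalized; <1e-4 of the mass lies outside, so the unit-sum
#: invariant holds exactly after renormalization.
GAUSSIAN_TRUNCATE = 4.0


class InvalidSpecError(ValueError):
    """A kernel or nonlinearity spec is internally inconsistent."""


@dataclass(frozen=True)
class KernelSpec:
    """Declarative description of a summation kernel.

    Parameters
    ----------
    kind:
        ``delta`` (Dirac delta / identity), ``box`` (constant kernel of
        ``size_px`` taps), ``gaussian`` (isotropic, std ``sigma_px``),
        ``dog`` (difference of two individually normalized Gaussians,
        ``sigma_px = (narrow, wide)``) or ``constant_full`` (a box spanning
        the whole signal; ``size_px`` may be left unset and inferred from
        the signal extent at realization time).
    size_px:
        Extent in pixels for ``box`` / ``constant_full``.
    sigma_px:
        Standard deviation in pixels (``gaussian``) or a ``(narrow, wide)``
        pair (``dog``).
    normalize:
        Normalize the realized kernel to unit sum.  Defaults to ``True``
        for every kind except ``dog`` (whose components are normalized
        individually before subtraction, so the difference sums to 0).
    """

    kind: KernelKind
    size_px: Optional[int] = None
    sigma_px: Union[None, float, Tuple[float, float]] = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "box", "gaussian", "dog", "constant_full"):
            raise InvalidSpecError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "box":
            if self.size_px is None or self.size_px <= 0:
                raise InvalidSpecError("box kernel requires a positive size_px")
        if self.kind == "constant_full" and self.size_px is not None and self.size_px <= 0:
            raise InvalidSpecError("constant_full size_px must be positive if given")
        if self.kind == "gaussian":
            if self.sigma_px is None or np.isscalar(self.sigma_px) is False or self.sigma_px <= 0:
                raise InvalidSpecError("gaussian kernel requires a positive scalar sigma_px")
        if self.kind == "dog":
            try:
                narrow, wide = self.sigma_px  # type: ignore[misc]
            except (TypeError, ValueError):
                raise InvalidSpecError("dog kernel requires sigma_px=(narrow, wide)") from None
            if narrow <= 0 or wide <= 0:
                raise InvalidSpecError("dog sigmas must be positive")
            if narrow >= wide:
                raise InvalidSpecError("dog requires narrow sigma < wide sigma")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("sigma_px"), tuple):
            d["sigma_px"] = list(d["sigma_px"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        if isinstance(d.get("sigma_px"), list):
            d["sigma_px"] = tuple(d["sigma_px"])
        return cls(**d)


@dataclass(frozen=True)
class NonlinearitySpec:
    """Declarative description of the pointwise nonlinearity ``sigma``.

    ``asymmetric_power`` is the odd-signed power law sigma(z) = z**p for
    z >= 0 and -|z|**q for z < 0 (the negative branch uses -|z|**q rather
    than (-z)**q so fractional exponents never produce complex values).
    ``piecewise_sinusoid`` is sigma(z) = sin(pi z) for |z| < 0.5 and
    sign(z)*sin(pi z)**2 otherwise — continuous at |z| = 0.5 where both
    branches give +/-1.  ``scaled_identity`` is sigma(z) = alpha*z and
    ``sign`` the hard sign function (histogram-equalization limit).
    """

    kind: SigmaKind = "asymmetric_power"
    p: float = 0.625
    q: float = 0.775
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("asymmetric_power", "piecewise_sinusoid", "scaled_identity", "sign"):
            raise InvalidSpecError(f"unknown nonlinearity kind {self.kind!r}")
        if self.kind == "asymmetric_power" and (self.p <= 0 or self.q <= 0):
            raise InvalidSpecError("asymmetric_power requires positive exponents")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NonlinearitySpec":
        return cls(**d)


_warned_even_extents: set = set()


def _odd(n: int) -> int:
    if n % 2 == 0:
        if n not in _warned_even_extents:  # warn once per extent
            _warned_even_extents.add(n)
            logger.warning("even kernel extent %d rounded up to %d", n, n + 1)
        return n + 1
    return n


def gaussian_taps(sigma: float) -> np.ndarray:
    """Normalized 1D Gaussian taps truncated at ±``GAUSSIAN_TRUNCATE``·sigma."""
    radius = int(GAUSSIAN_TRUNCATE * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def realize_kernel(
    spec: KernelSpec,
    ndim: int,
    signal_extent: Optional[int] = None,
) -> np.ndarray:
    """Realize a :class:`KernelSpec` as a centered odd-extent grid.

    Parameters
    ----------
    spec:
        The kernel description.
    ndim:
        1 or 2; the dimensionality of the signal the kernel will act on.
        2D kernels are separable outer products of the 1D taps (box →
        square, gaussian → isotropic), except the delta.
    signal_extent:
        Required for ``constant_full`` when ``spec.size_px`` is unset: the
        extent (in pixels) of the signal the kernel should span.
    """
    if ndim not in (1, 2):
        raise InvalidSpecError("ndim must be 1 or 2")

    if spec.kind == "delta":
        k1 = np.array([0.0, 1.0, 0.0])
    elif spec.kind in ("box", "constant_full"):
        size = spec.size_px
        if size is None:
            if spec.kind == "constant_full" and signal_extent is not None:
                size = int(signal_extent)
            else:
                raise InvalidSpecError(f"{spec.kind} kernel requires size_px or signal_extent")
        size = _odd(int(size))
        k1 = np.full(size, 1.0 / size)
    elif spec.kind == "gaussian":
        k1 = gaussian_taps(float(spec.sigma_px))  # type: ignore[arg-type]
    elif spec.kind == "dog":
        narrow, wide = spec.sigma_px  # type: ignore[misc]
        kn, kw = gaussian_taps(float(narrow)), gaussian_taps(float(wide))
        if ndim == 1:
            return _embed_diff(kn, kw)
        return _embed_diff(np.outer(kn, kn), np.outer(kw, kw))
    else:  # pragma: no cover - guarded in __post_init__
        raise InvalidSpecError(f"unknown kernel kind {spec.kind!r}")

    if ndim == 2:
        k = np.outer(k1, k1)
    else:
        k = k1.copy()
    # delta and box taps are exactly normalized by construction; dividing by
    # their float sum would perturb the exact 1/s entries
    if spec.normalize and spec.kind == "gaussian":
        k = k / k.sum()
    return k


def _embed_diff(kn: np.ndarray, kw: np.ndarray) -> np.ndarray:
    """Center-embed the narrow Gaussian into the wide one's grid and subtract."""
    out = -kw.copy()
    slices = tuple(
        slice((wn - nn) // 2, (wn - nn) // 2 + nn) for wn, nn in zip(kw.shape, kn.shape)
    )
    out[slices] += kn
    return out


def eval_sigma(spec: NonlinearitySpec, z):
    """Evaluate the nonlinearity elementwise; scalars in, scalar out."""
    scalar = np.isscalar(z)
    z = np.asarray(z, dtype=float)
    if spec.kind == "asymmetric_power":
        out = np.where(z >= 0, np.abs(z) ** spec.p, -(np.abs(z) ** spec.q))
    elif spec.kind == "piecewise_sinusoid":
        s = np.sin(np.pi * z)
        out = np.where(np.abs(z) < 0.5, s, np.sign(z) * s * s)
    elif spec.kind == "scaled_identity":
        out = spec.alpha * z
    elif spec.kind == "sign":
        out = np.sign(z)
    else:  # pragma: no cover
        raise InvalidSpecError(f"unknown nonlinearity kind {spec.kind!r}")
    return float(out) if scalar else out
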