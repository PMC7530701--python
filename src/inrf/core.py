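"""The intrinsically nonlinear receptive field (INRF) operator.

The classical linear receptive field (RF) models a neuron's response as a
weighted sum of the input, ``LRF(x) = sum_i w_i I(y_i)``; the
linear–nonlinear subunit variant applies a pointwise nonlinearity first,
``LNRF(x) = sum_i w_i sigma(I(y_i))``.  The INRF extends these with a
nonlinear-dendrite term whose nonlinearity is *shifted* by a local average
of the signal around the output location::

    INRF(x) = sum_i m_i I(y_i) - lambda * sum_i w_i sigma(I(y_i) - (g*I)(x))

Because the argument of ``sigma`` depends on the output location ``x``
through ``(g*I)(x)``, the operator is not a convolution followed by a
pointwise map: the same neighbor is transformed differently when it
contributes to different output points.  Expressing it with linear filters
would require one filter per pixel (``N + 2`` convolutions for a single
output point on an ``N``-pixel image; :func:`count_lnl_filters`).

Two evaluators are provided with the same mathematical contract:

* :func:`inrf_oracle` — the literal double loop over output locations and
  kernel taps.  Slow, used as the correctness reference.
* :func:`inrf_apply` — a level-decomposition evaluator in the spirit of
  constant-time bilateral filtering: the shifted-nonlinearity term is a
  convolution ``w * sigma(I - c)`` for each distinct value ``c`` of the
  local mean ``g*I``, so stacking one convolution per level and reading
  (or linearly interpolating) the stack at ``c(x)`` reproduces the operator
  exactly on piecewise-constant inputs and to interpolation accuracy
  otherwise.

Also here: the comparison operators :func:`lrf_apply`, :func:`lnrf_apply`,
the linear+nonlinear (L+NL) baseline :func:`lnl_apply`, and
:func:`reduce_to_linear`, the closed-form collapse of the INRF to a single
linear kernel when ``sigma`` is a pure scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple, Union

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import fftconvolve

from .primitives import (
    InvalidSpecError,
    KernelSpec,
    NonlinearitySpec,
    eval_sigma,
    gaussian_taps,
    realize_kernel,
)

__all__ = [
    "Boundary",
    "Raster",
    "INRFParams",
    "LNLParams",
    "inrf_oracle",
    "inrf_apply",
    "lrf_apply",
    "lnrf_apply",
    "lnl_apply",
    "reduce_to_linear",
    "count_lnl_filters",
    "apply_kernel",
]

Boundary = Literal["mirror", "replicate", "periodic", "zero"]

# "mirror" is symmetric (edge-inclusive) reflection: the padding of [0,1,0]
# on the left reads 0, not 1.
_NP_PAD = {"mirror": "symmetric", "replicate": "edge", "periodic": "wrap", "zero": "constant"}
_NDI_MODE = {"mirror": "reflect", "replicate": "nearest", "periodic": "wrap", "zero": "constant"}

# Above this many multiply-accumulates a 1D correlation switches from the
# direct ndimage path to FFT.
_DIRECT_MAC_LIMIT = 3e7


@dataclass
class Raster:
    """A 1D signal or 2D image with display metadata.

    ``values`` are double precision, row-major, with pixel centers at
    integer coordinates.  ``value_range`` is the nominal [lo, hi] the data
    lives in (used by I/O for integer encoding); ``pixels_per_degree``
    relates pixels to visual angle when known.
    """

    values: np.ndarray
    value_range: Tuple[float, float] = (0.0, 1.0)
    pixels_per_degree: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("Raster values must be non-empty")
        if self.values.ndim not in (1, 2):
            raise ValueError("Raster must be 1D or 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Raster values must be finite")

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.value_range, self.pixels_per_degree)


@dataclass(frozen=True)
class INRFParams:
    """Full specification of one INRF operator instance."""

    m: KernelSpec
    w: KernelSpec
    g: KernelSpec
    lambda_weight: float
    sigma: NonlinearitySpec
    boundary: Boundary = "mirror"

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_weight):
            raise InvalidSpecError("lambda_weight must be finite")
        if self.boundary not in _NP_PAD:
            raise InvalidSpecError(f"unknown boundary {self.boundary!r}")


@dataclass(frozen=True)
class LNLParams:
    """Linear + nonlinear baseline: ``m*I - lambda * sigma(DoG*I)``.

    ``dog_sign`` selects the center polarity of the difference of
    Gaussians: ``+1`` is center-positive (narrow minus wide), ``-1``
    center-negative (wide minus narrow).  The brightness-perception fits
    use the center-negative orientation, which is the one that yields
    brightness increasing with luminance under the ``-lambda*sigma``
    coupling.
    """

    m: KernelSpec
    dog: KernelSpec
    lambda_weight: float
    sigma: NonlinearitySpec
    boundary: Boundary = "mirror"
    dog_sign: float = 1.0

    def __post_init__(self) -> None:
        if self.dog.kind != "dog":
            raise InvalidSpecError("LNLParams.dog must have kind 'dog'")
        if self.dog_sign not in (1.0, -1.0):
            raise InvalidSpecError("dog_sign must be +1 or -1")


def _values(I) -> np.ndarray:
    if isinstance(I, Raster):
        return I.values
    x = np.asarray(I, dtype=float)
    if x.ndim not in (1, 2):
        raise ValueError("input must be 1D or 2D")
    return x


def _like(I, values: np.ndarray):
    if isinstance(I, Raster):
        return I.with_values(values)
    return values


def _pad(x: np.ndarray, radii: Tuple[int, ...], boundary: Boundary) -> np.ndarray:
    pad = [(r, r) for r in radii]
    if boundary == "zero":
        return np.pad(x, pad, mode="constant", constant_values=0.0)
    return np.pad(x, pad, mode=_NP_PAD[boundary])


_KERNEL_FFT_CACHE: dict = {}


def _corr1d(x: np.ndarray, taps: np.ndarray, axis: int, boundary: Boundary,
            cval: float = 0.0) -> np.ndarray:
    """Centered correlation with odd-length ``taps`` along one axis.

    Direct (ndimage) for small problems; for large ones a circular FFT
    convolution of the boundary-padded signal at the minimal
    alias-free length (overlap-save), with the kernel transform cached.
    Both paths honor the boundary policy exactly.
    """
    if x.size * taps.size <= _DIRECT_MAC_LIMIT:
        return ndi.correlate1d(x, taps, axis=axis, mode=_NDI_MODE[boundary], cval=cval)
    from scipy.fft import irfft, next_fast_len, rfft

    n = x.shape[axis]
    k = taps.size
    r = k // 2
    pad = [(0, 0)] * x.ndim
    pad[axis] = (r, r)
    if boundary == "zero":
        xp = np.pad(x, pad, mode="constant", constant_values=cval)
    else:
        xp = np.pad(x, pad, mode=_NP_PAD[boundary])
    # padded length is n + k - 1, exactly the alias-free circular size for
    # the n valid outputs
    nfft = next_fast_len(n + k - 1)
    key = (taps.tobytes(), nfft)
    kf = _KERNEL_FFT_CACHE.get(key)
    if kf is None:
        kf = rfft(taps[::-1], nfft)
        if len(_KERNEL_FFT_CACHE) > 64:
            _KERNEL_FFT_CACHE.clear()
        _KERNEL_FFT_CACHE[key] = kf
    xp = np.moveaxis(xp, axis, -1)
    shape = (1,) * (xp.ndim - 1) + (kf.size,)
    full = irfft(rfft(xp, nfft, axis=-1) * kf.reshape(shape), nfft, axis=-1)
    out = full[..., k - 1:k - 1 + n]
    return np.ascontiguousarray(np.moveaxis(out, -1, axis))


def _conv_spec(x: np.ndarray, spec: KernelSpec, boundary: Boundary,
               spatial_ndim: Optional[int] = None, cval: float = 0.0) -> np.ndarray:
    """Correlate ``x`` with the realized kernel along its trailing spatial axes.

    Leading axes (e.g. a level stack) are treated as batch dimensions.
    Separable kinds (box, gaussian, dog components) are applied axis by
    axis, which is exactly equivalent to correlation with the realized
    outer-product grid.
    """
    if spatial_ndim is None:
        spatial_ndim = x.ndim
    axes = list(range(x.ndim - spatial_ndim, x.ndim))
    if spec.kind == "delta":
        return x.astype(float, copy=True)
    if spec.kind == "dog":
        narrow, wide = spec.sigma_px  # type: ignore[misc]
        out = x.astype(float, copy=True)
        out_w = x.astype(float, copy=True)
        for ax in axes:
            out = _corr1d(out, gaussian_taps(float(narrow)), ax, boundary, cval)
            out_w = _corr1d(out_w, gaussian_taps(float(wide)), ax, boundary, cval)
        return out - out_w
    if spec.kind == "gaussian":
        taps = gaussian_taps(float(spec.sigma_px))  # type: ignore[arg-type]
        out = x.astype(float, copy=True)
        for ax in axes:
            out = _corr1d(out, taps, ax, boundary, cval)
        return out
    if spec.kind in ("box", "constant_full"):
        out = x.astype(float, copy=True)
        for ax in axes:
            taps = realize_kernel(spec, 1, signal_extent=x.shape[ax])
            out = _corr1d(out, taps, ax, boundary, cval)
        return out
    raise InvalidSpecError(f"unknown kernel kind {spec.kind!r}")  # pragma: no cover


def apply_kernel(I, kernel: np.ndarray, boundary: Boundary = "mirror"):
    """Correlate a signal with an explicit realized kernel grid."""
    x = _values(I)
    k = np.asarray(kernel, dtype=float)
    if k.ndim != x.ndim:
        raise ValueError(f"kernel ndim {k.ndim} does not match signal ndim {x.ndim}")
    out = ndi.correlate(x, k, mode=_NDI_MODE[boundary], cval=0.0)
    return _like(I, out)


# ---------------------------------------------------------------------------
# Reference evaluator
# ---------------------------------------------------------------------------

def inrf_oracle(I, params: INRFParams):
    """Literal per-pixel evaluation of the INRF summation.

    For every output location ``x`` this walks the taps of ``m``, ``w`` and
    ``g`` explicitly: ``out(x) = sum_i m_i I(y_i) -
    lambda * sum_i w_i sigma(I(y_i) - (g*I)(x))`` with out-of-grid
    neighbors supplied by the boundary policy.  Reference implementation —
    no speed guarantee; use :func:`inrf_apply` for anything large.
    """
    x = _values(I)
    ndim = x.ndim
    ext = x.shape[0]
    m = realize_kernel(params.m, ndim, signal_extent=ext)
    w = realize_kernel(params.w, ndim, signal_extent=ext)
    g = realize_kernel(params.g, ndim, signal_extent=ext)
    pm = _pad(x, tuple(s // 2 for s in m.shape), params.boundary)
    pw = _pad(x, tuple(s // 2 for s in w.shape), params.boundary)
    pg = _pad(x, tuple(s // 2 for s in g.shape), params.boundary)
    lam = params.lambda_weight
    out = np.empty_like(x)
    for idx in np.ndindex(x.shape):
        win_g = pg[tuple(slice(i, i + s) for i, s in zip(idx, g.shape))]
        c = float(np.sum(g * win_g))
        win_m = pm[tuple(slice(i, i + s) for i, s in zip(idx, m.shape))]
        lin = float(np.sum(m * win_m))
        win_w = pw[tuple(slice(i, i + s) for i, s in zip(idx, w.shape))]
        nl = float(np.sum(w * eval_sigma(params.sigma, win_w - c)))
        out[idx] = lin - lam * nl
    return _like(I, out)


# ---------------------------------------------------------------------------
# Fast evaluator
# ---------------------------------------------------------------------------

def inrf_apply(I, params: INRFParams, levels: Union[int, str] = "auto"):
    """Evaluate the INRF by decomposition over levels of the local mean.

    ``c = g*I`` is computed once; for each level ``c_l`` the shifted term
    ``T_l = w * sigma(I - c_l)`` is an ordinary convolution, and the
    operator output at ``x`` reads the stack at ``c(x)``.  When ``c`` takes
    at most ``levels`` distinct values the decomposition is exact;
    otherwise ``levels`` uniformly spaced values spanning ``[min c, max c]``
    are used and the read is a linear interpolation between the bracketing
    levels.

    Parameters
    ----------
    levels:
        ``"auto"`` (use 64) or an integer >= 2.
    """
    if levels == "auto":
        n_levels = 64
    else:
        n_levels = int(levels)
        if n_levels < 2:
            raise ValueError("levels must be >= 2")
    x = _values(I)
    boundary = params.boundary
    lam = params.lambda_weight

    c = _conv_spec(x, params.g, boundary)
    m_term = _conv_spec(x, params.m, boundary)

    lv = np.unique(c)
    if lv.size > n_levels:
        lv = np.linspace(float(c.min()), float(c.max()), n_levels)

    if lv.size == 1:
        sig = eval_sigma(params.sigma, x - lv[0])
        cval = eval_sigma(params.sigma, -lv[0]) if boundary == "zero" else 0.0
        R = _conv_spec(sig, params.w, boundary, cval=cval)
        return _like(I, m_term - lam * R)

    T = np.empty((lv.size,) + x.shape)
    if boundary == "zero":
        # the padding value of the sigma field differs per level
        for j, l in enumerate(lv):
            sig = eval_sigma(params.sigma, x - l)
            T[j] = _conv_spec(sig, params.w, boundary,
                              cval=float(eval_sigma(params.sigma, -l)))
    else:
        # chunk the level stack to bound the FFT working set
        chunk = max(1, int(4e6 // max(x.size, 1)))
        for j0 in range(0, lv.size, chunk):
            sub = lv[j0:j0 + chunk]
            diffs = x[None] - sub.reshape((-1,) + (1,) * x.ndim)
            T[j0:j0 + chunk] = _conv_spec(eval_sigma(params.sigma, diffs),
                                          params.w, boundary, spatial_ndim=x.ndim)

    hi = np.clip(np.searchsorted(lv, c), 1, lv.size - 1)
    lo = hi - 1
    span = lv[hi] - lv[lo]
    t = np.clip((c - lv[lo]) / np.where(span > 0, span, 1.0), 0.0, 1.0)
    Tf = T.reshape(lv.size, -1)
    cols = np.arange(Tf.shape[1])
    R = (Tf[lo.ravel(), cols] * (1.0 - t.ravel())
         + Tf[hi.ravel(), cols] * t.ravel()).reshape(x.shape)
    return _like(I, m_term - lam * R)


# ---------------------------------------------------------------------------
# Comparison operators
# ---------------------------------------------------------------------------

def lrf_apply(I, kernel: KernelSpec, boundary: Boundary = "mirror"):
    """Classical linear receptive field: plain correlation with the kernel."""
    x = _values(I)
    return _like(I, _conv_spec(x, kernel, boundary))


def lnrf_apply(I, kernel: KernelSpec, sigma: NonlinearitySpec,
               boundary: Boundary = "mirror"):
    """Nonlinear-subunit summation: ``sum_i w_i sigma(I(y_i))``."""
    x = _values(I)
    return _like(I, _conv_spec(eval_sigma(sigma, x), kernel, boundary))


def lnl_apply(I, params: LNLParams):
    """L+NL baseline: ``m*I - lambda * sigma(DoG*I)`` (sigma after the DoG)."""
    x = _values(I)
    m_term = _conv_spec(x, params.m, params.boundary)
    z = params.dog_sign * _conv_spec(x, params.dog, params.boundary)
    return _like(I, m_term - params.lambda_weight * eval_sigma(params.sigma, z))


def reduce_to_linear(params: INRFParams, alpha: float, ndim: int = 1,
                     signal_extent: Optional[int] = None) -> np.ndarray:
    """Collapse the INRF with ``sigma(z) = alpha*z`` to one linear kernel.

    Returns the realized grid ``k = m - lambda*alpha*w +
    lambda*alpha*(sum_i w_i)*g`` with the three kernels zero-padded to a
    common centered extent.  Correlating the input with ``k`` reproduces
    the INRF output exactly in that regime; with Gaussian ``m``, ``g`` and
    a wider Gaussian ``w`` the result has the center-surround sign
    structure of a difference-of-Gaussians RF.
    """
    m = realize_kernel(params.m, ndim, signal_extent=signal_extent)
    w = realize_kernel(params.w, ndim, signal_extent=signal_extent)
    g = realize_kernel(params.g, ndim, signal_extent=signal_extent)
    shape = tuple(max(a, b, c) for a, b, c in zip(m.shape, w.shape, g.shape))
    la = params.lambda_weight * alpha
    k = _embed(m, shape) - la * _embed(w, shape) + la * float(w.sum()) * _embed(g, shape)
    return k


def _embed(k: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    out = np.zeros(shape)
    slices = tuple(slice((s - n) // 2, (s - n) // 2 + n) for s, n in zip(shape, k.shape))
    out[slices] = k
    return out


def count_lnl_filters(n_pixels: int) -> int:
    """Convolutions needed to express one INRF output point in L+NL form.

    One single-tap-difference filter per neighbor, plus the final ``w``
    correlation, plus the ``m`` correlation: ``N + 2`` for an ``N``-pixel
    image.  At one megapixel this exceeds a million linear filters.
    """
    n = int(n_pixels)
    if n < 1:
        raise ValueError("n_pixels must be >= 1")
    return n + 2
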