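"""The INRF operator: reference evaluator, fast path, comparison models."""

import numpy as np
import pytest

from inrf.core import (
    INRFParams,
    LNLParams,
    Raster,
    apply_kernel,
    count_lnl_filters,
    inrf_apply,
    inrf_oracle,
    lnl_apply,
    lnrf_apply,
    lrf_apply,
    reduce_to_linear,
)
from inrf.primitives import KernelSpec, NonlinearitySpec

DELTA = KernelSpec(kind="delta")
CUBE = NonlinearitySpec(kind="asymmetric_power", p=3.0, q=3.0)  # sigma(z) = z^3


def test_oracle_hand_computed_center_value():
    """[0,1,0], delta m and g, box-3 w, lambda 1, sigma z^3: the center sees
    sigma(-1)+sigma(0)+sigma(-1) averaged = -2/3, so output = 1 + 2/3."""
    params = INRFParams(m=DELTA, w=KernelSpec(kind="box", size_px=3), g=DELTA,
                        lambda_weight=1.0, sigma=CUBE)
    out = inrf_oracle(np.array([0.0, 1.0, 0.0]), params)
    assert out[1] == pytest.approx(5.0 / 3.0, abs=1e-12)


@pytest.mark.parametrize("c", [0.0, 0.37, 1.0])
def test_constant_image_is_fixed_point(c, small_inrf_params):
    out = inrf_apply(np.full((9, 9), c), small_inrf_params)
    assert np.allclose(out, c, atol=1e-12)
    out1 = inrf_oracle(np.full(17, c), small_inrf_params)
    assert np.allclose(out1, c, atol=1e-12)


@pytest.mark.parametrize("boundary", ["mirror", "replicate", "periodic", "zero"])
@pytest.mark.parametrize("w_kind", [
    KernelSpec(kind="gaussian", sigma_px=4.0),
    KernelSpec(kind="box", size_px=7),
])
def test_fast_path_exact_on_piecewise_constant(boundary, w_kind, rng):
    """With g*I taking few distinct values the level decomposition is exact."""
    params = INRFParams(m=KernelSpec(kind="gaussian", sigma_px=2.0), w=w_kind,
                        g=DELTA, lambda_weight=3.875,
                        sigma=NonlinearitySpec(kind="asymmetric_power"),
                        boundary=boundary)
    x = rng.choice([0.1, 0.45, 0.9], size=(14, 14))
    fast = inrf_apply(x, params)
    ref = inrf_oracle(x, params)
    assert np.max(np.abs(fast - ref)) < 1e-10


def test_fast_path_exact_with_smoothing_g(rng):
    """A non-delta g also stays exact when its output has few levels."""
    params = INRFParams(m=DELTA, w=KernelSpec(kind="box", size_px=5),
                        g=KernelSpec(kind="box", size_px=3),
                        lambda_weight=1.0, sigma=CUBE)
    x = rng.choice([0.0, 1.0], size=24)
    fast = inrf_apply(x, params, levels=64)
    ref = inrf_oracle(x, params)
    assert np.max(np.abs(fast - ref)) < 1e-10


def test_fast_path_interpolation_accuracy(rng, small_inrf_params):
    x = rng.random((24, 24))
    fast = inrf_apply(x, small_inrf_params, levels=64)
    ref = inrf_oracle(x, small_inrf_params)
    assert np.max(np.abs(fast - ref)) < 1e-3


def test_levels_argument_validated(small_inrf_params):
    with pytest.raises(ValueError):
        inrf_apply(np.zeros(8), small_inrf_params, levels=1)


def test_lrf_identity_and_box_and_mass():
    assert np.allclose(lrf_apply(np.array([3.0, 1.0, 2.0]), DELTA),
                       [3.0, 1.0, 2.0])
    out = lrf_apply(np.array([0.0, 1.0, 0.0]), KernelSpec(kind="box", size_px=3),
                    boundary="mirror")
    assert np.allclose(out, [1 / 3, 1 / 3, 1 / 3], atol=1e-14)
    const = lrf_apply(np.full((8, 8), 0.7), KernelSpec(kind="gaussian", sigma_px=2.0))
    assert np.allclose(const, 0.7, atol=1e-12)


def test_lnrf_reduces_to_lrf_for_identity_sigma(rng):
    kernel = KernelSpec(kind="gaussian", sigma_px=1.5)
    x = rng.random(20)
    a = lnrf_apply(x, kernel, NonlinearitySpec(kind="scaled_identity", alpha=1.0))
    b = lrf_apply(x, kernel)
    assert np.allclose(a, b, atol=1e-14)


def test_lnrf_hand_example_and_constant():
    square = NonlinearitySpec(kind="asymmetric_power", p=2.0, q=2.0)
    # sigma is odd-signed, so with nonnegative input it is plain z^2
    out = lnrf_apply(np.array([0.0, 1.0, 0.0]), KernelSpec(kind="box", size_px=3),
                     square, boundary="mirror")
    assert out[1] == pytest.approx(1 / 3, abs=1e-14)
    c = lnrf_apply(np.full(9, 0.6), KernelSpec(kind="gaussian", sigma_px=1.0),
                   NonlinearitySpec(kind="asymmetric_power"))
    assert np.allclose(c, 0.6 ** 0.625, atol=1e-12)


def test_lnl_lambda_zero_is_linear_and_constant_fixed_point(rng):
    params = LNLParams(m=KernelSpec(kind="gaussian", sigma_px=2.0),
                       dog=KernelSpec(kind="dog", sigma_px=(2.0, 4.0)),
                       lambda_weight=0.0,
                       sigma=NonlinearitySpec(kind="asymmetric_power"))
    x = rng.random(30)
    assert np.allclose(lnl_apply(x, params),
                       lrf_apply(x, params.m), atol=1e-14)
    params2 = LNLParams(m=params.m, dog=params.dog, lambda_weight=2.0,
                        sigma=params.sigma)
    # the DoG has zero mass, so a constant image passes through unchanged
    assert np.allclose(lnl_apply(np.full(40, 0.3), params2), 0.3, atol=1e-12)


def test_reduce_to_linear_matches_oracle(rng):
    """Eq.-8 regime: with sigma = alpha*z the INRF is one convolution."""
    for _ in range(5):
        alpha = float(rng.uniform(0.2, 1.5))
        lam = float(rng.uniform(0.0, 3.0))
        params = INRFParams(
            m=KernelSpec(kind="gaussian", sigma_px=float(rng.uniform(1, 3))),
            w=KernelSpec(kind="gaussian", sigma_px=float(rng.uniform(3, 6))),
            g=KernelSpec(kind="gaussian", sigma_px=float(rng.uniform(0.5, 1.5))),
            lambda_weight=lam,
            sigma=NonlinearitySpec(kind="scaled_identity", alpha=alpha),
        )
        k = reduce_to_linear(params, alpha, ndim=1)
        for _ in range(4):
            x = rng.random(40)
            assert np.max(np.abs(apply_kernel(x, k) - inrf_oracle(x, params))) < 1e-10


def test_reduce_to_linear_lambda_zero_returns_m():
    params = INRFParams(m=KernelSpec(kind="gaussian", sigma_px=2.0),
                        w=KernelSpec(kind="gaussian", sigma_px=4.0), g=DELTA,
                        lambda_weight=0.0,
                        sigma=NonlinearitySpec(kind="scaled_identity"))
    k = reduce_to_linear(params, 1.0, ndim=1)
    from inrf.primitives import realize_kernel

    m = realize_kernel(params.m, 1)
    pad = (k.size - m.size) // 2
    assert np.allclose(k, np.pad(m, pad), atol=1e-15)


def test_reduce_to_linear_center_surround_structure():
    """Gaussian m, g with a wider gaussian w collapse to a DoG-like kernel."""
    params = INRFParams(m=KernelSpec(kind="gaussian", sigma_px=2.0),
                        w=KernelSpec(kind="gaussian", sigma_px=6.0),
                        g=KernelSpec(kind="gaussian", sigma_px=1.0),
                        lambda_weight=2.0,
                        sigma=NonlinearitySpec(kind="scaled_identity", alpha=1.0))
    k = reduce_to_linear(params, 1.0, ndim=2)
    c = tuple(s // 2 for s in k.shape)
    assert k[c] > 0
    assert k.min() < 0  # inhibitory surround
    # the negative lobe surrounds the center: check along the midline
    row = k[c[0]]
    assert row[c[1] + 10] < 0 < row[c[1]]


@pytest.mark.parametrize("n,expected", [(1, 3), (512, 514), (10 ** 6, 1_000_002)])
def test_filter_count_is_n_plus_two(n, expected):
    assert count_lnl_filters(n) == expected
    if n == 10 ** 6:
        assert count_lnl_filters(n) > 10 ** 6


def test_filter_count_validates():
    with pytest.raises(ValueError):
        count_lnl_filters(0)


def test_operator_is_not_homogeneous(rng, small_inrf_params):
    """With a non-unit power sigma, doubling the input does not double the
    output anywhere-dense — no single linear kernel reproduces the operator."""
    x = rng.random((12, 12))
    a = np.asarray(inrf_apply(2 * x, small_inrf_params, levels=128))
    b = 2 * np.asarray(inrf_apply(x, small_inrf_params, levels=128))
    assert np.max(np.abs(a - b)) > 0.01


def test_translation_equivariance_under_periodic_boundary(rng):
    params = INRFParams(m=KernelSpec(kind="gaussian", sigma_px=1.5),
                        w=KernelSpec(kind="box", size_px=5), g=DELTA,
                        lambda_weight=1.3,
                        sigma=NonlinearitySpec(kind="asymmetric_power"),
                        boundary="periodic")
    x = rng.choice([0.2, 0.5, 0.8], size=32)
    shifted = inrf_apply(np.roll(x, 7), params)
    assert np.allclose(shifted, np.roll(np.asarray(inrf_apply(x, params)), 7),
                       atol=1e-12)


def test_raster_validation():
    with pytest.raises(ValueError):
        Raster(np.array([np.nan, 1.0]))
    with pytest.raises(ValueError):
        Raster(np.zeros((2, 2, 2)))
    with pytest.raises(ValueError):
        Raster(np.empty(0))
    r = Raster(np.zeros((4, 4)), value_range=(0, 1), pixels_per_degree=64)
    out = inrf_apply(r, INRFParams(m=DELTA, w=DELTA, g=DELTA, lambda_weight=1.0,
                                   sigma=NonlinearitySpec(kind="asymmetric_power")))
    assert isinstance(out, Raster)
    assert out.pixels_per_degree == 64
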