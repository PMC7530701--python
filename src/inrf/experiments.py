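"""The four vision-science pipelines.

Each pipeline assembles stimuli, a photoreceptor front end and one fixed
INRF instance into the published response curves and illusion statistics:

* :func:`run_onoff` — a simulated retinal cell's rectified center response
  to a gray segment on a bar background; at low stimulus spatial frequency
  the cell responds only below the mean level (OFF behavior), at high
  frequency only above it (ON behavior), with a single fixed operator.
* :func:`run_crispening` — brightness-scaling curves over uniform and
  salt-and-pepper backgrounds; the slope of the curve peaks at the
  background luminance for uniform surrounds (crispening) and not for
  salt-and-pepper ones.  The linear+nonlinear baseline with either printed
  fit cannot reproduce both conditions.
* :func:`run_white` — strength of White's illusion under added one-octave
  bandpass noise, averaged over seeded realizations.
* :func:`run_irradiation` — the irradiation illusion: a white figure on
  black ground comes out wider than the equal-size black figure on white.

The 1D pipelines evaluate the INRF with the exact brute-force evaluator
(signals are short); the 2D pipelines use the level-decomposition fast
path, which is exact on these piecewise-constant displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np

from .core import INRFParams, LNLParams, Raster, inrf_apply, inrf_oracle, lnl_apply
from .front_end import crispening_semisaturation, naka_rushton, power_law, retinal_blur
from .primitives import KernelSpec, NonlinearitySpec
from .stimuli import (
    BrightnessDisplayConfig,
    OnOffConfig,
    WhiteStimulusConfig,
    display_circle_centers,
    make_brightness_display,
    make_irradiation_signal,
    make_onoff_stimulus,
    make_white_stimulus,
    white_patch_masks,
)

__all__ = [
    "ONOFF_INRF",
    "INRF_B",
    "WHITE_INRF",
    "IRRADIATION_INRF",
    "LNL_UNIFORM_FIT",
    "LNL_SALTPEPPER_FIT",
    "UNIFORM_BACKGROUNDS",
    "SALT_PEPPER_FRACTIONS",
    "ResponseCurve",
    "BrightnessCurve",
    "IllusionStrengthResult",
    "IrradiationResult",
    "run_onoff",
    "run_crispening",
    "slope_peak_statistic",
    "run_white",
    "run_irradiation",
]

# ---------------------------------------------------------------------------
# Fixed parameter sets
# ---------------------------------------------------------------------------

#: ON/OFF cell: constant m and g of 85 taps, w spanning the whole signal,
#: lambda = 1000, sinusoidal sigma.
ONOFF_INRF = INRFParams(
    m=KernelSpec(kind="box", size_px=85),
    w=KernelSpec(kind="constant_full"),
    g=KernelSpec(kind="box", size_px=85),
    lambda_weight=1000.0,
    sigma=NonlinearitySpec(kind="piecewise_sinusoid"),
)

#: INRF-B, the brightness-perception operator shared by the crispening and
#: image-quality pipelines: Gaussian m (0.81 deg = 52 px) and w (2.77 deg =
#: 178 px), delta g, lambda = 3.875, asymmetric power sigma (0.625 / 0.775).
INRF_B = INRFParams(
    m=KernelSpec(kind="gaussian", sigma_px=52.0),
    w=KernelSpec(kind="gaussian", sigma_px=178.0),
    g=KernelSpec(kind="delta"),
    lambda_weight=3.875,
    sigma=NonlinearitySpec(kind="asymmetric_power", p=0.625, q=0.775),
)

#: Same operator in the slightly different pixel metric of the White's
#: illusion stimuli (54 / 183 px for the same visual angles).
WHITE_INRF = INRFParams(
    m=KernelSpec(kind="gaussian", sigma_px=54.0),
    w=KernelSpec(kind="gaussian", sigma_px=183.0),
    g=KernelSpec(kind="delta"),
    lambda_weight=3.875,
    sigma=NonlinearitySpec(kind="asymmetric_power", p=0.625, q=0.775),
)

#: Irradiation pipeline metric: 100 / 342 px.
IRRADIATION_INRF = INRFParams(
    m=KernelSpec(kind="gaussian", sigma_px=100.0),
    w=KernelSpec(kind="gaussian", sigma_px=342.0),
    g=KernelSpec(kind="delta"),
    lambda_weight=3.875,
    sigma=NonlinearitySpec(kind="asymmetric_power", p=0.625, q=0.775),
)

#: L+NL baseline fitted to the uniform-background condition (center-negative
#: DoG: the orientation for which brightness increases with luminance).
LNL_UNIFORM_FIT = LNLParams(
    m=KernelSpec(kind="gaussian", sigma_px=52.0),
    dog=KernelSpec(kind="dog", sigma_px=(30.0, 60.0), normalize=False),
    lambda_weight=2.0,
    sigma=NonlinearitySpec(kind="asymmetric_power", p=0.5, q=0.7),
    dog_sign=-1.0,
)

#: L+NL baseline fitted to the salt-and-pepper condition.
LNL_SALTPEPPER_FIT = LNLParams(
    m=KernelSpec(kind="gaussian", sigma_px=52.0),
    dog=KernelSpec(kind="dog", sigma_px=(40.0, 50.0), normalize=False),
    lambda_weight=10.0,
    sigma=NonlinearitySpec(kind="asymmetric_power", p=0.9, q=0.9),
    dog_sign=-1.0,
)

#: Uniform background luminances of the brightness-scaling experiment, cd/m^2.
UNIFORM_BACKGROUNDS = (0.65, 19.24, 37.83, 56.41, 75.00)

#: Black-pixel fractions of the salt-and-pepper condition.  Their mean
#: luminances match the uniform levels; 0 and 1 are degenerate (they *are*
#: the uniform white/black backgrounds).
SALT_PEPPER_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)

NAKA_RUSHTON_N = 0.74


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class ResponseCurve:
    """Rectified center response ``v`` versus center input value ``u``."""

    u: np.ndarray
    v: np.ndarray
    bar_width: int

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same length")
        if np.any(self.v < 0):
            raise ValueError("rectified responses must be nonnegative")


@dataclass
class BrightnessCurve:
    """Model output at the 11 circle centers versus circle luminance."""

    background_kind: str
    background_level: float       # cd/m^2 (uniform) or black fraction
    mean_luminance: float         # image mean, cd/m^2
    circle_luminances: np.ndarray
    outputs: np.ndarray

    def __post_init__(self) -> None:
        self.circle_luminances = np.asarray(self.circle_luminances, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.circle_luminances.shape != self.outputs.shape or len(self.outputs) != 11:
            raise ValueError("a brightness curve has 11 matched points")
        if not np.all(np.isfinite(self.outputs)):
            raise ValueError("model outputs must be finite")


@dataclass
class IllusionStrengthResult:
    """Illusion strength statistics at one noise band."""

    center_freq_cpd: float
    mean_strength: float
    sd: float
    n_realizations: int
    strengths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class IrradiationResult:
    """Clipped response profiles and apparent widths for both polarities."""

    profiles: Dict[str, np.ndarray]
    widths: Dict[str, int]


# ---------------------------------------------------------------------------
# ON/OFF polarity reversal
# ---------------------------------------------------------------------------

def run_onoff(bar_width: int, u_grid: Optional[Sequence[float]] = None,
              params: INRFParams = ONOFF_INRF, blur_sigma: float = 4.0) -> ResponseCurve:
    """Sweep the center value ``u`` and record the rectified center response.

    For each ``u``: build the bar stimulus, blur with a Gaussian of std
    ``blur_sigma`` (retinal blur), apply the fixed INRF, half-wave rectify,
    and read the center sample.
    """
    if u_grid is None:
        u_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    u_grid = np.asarray(u_grid, dtype=float)
    v = np.empty_like(u_grid)
    for i, u in enumerate(u_grid):
        cfg = OnOffConfig(bar_width=bar_width, center_value=float(u),
                          blur_sigma=blur_sigma)
        stim = make_onoff_stimulus(cfg)
        blurred = retinal_blur(stim, blur_sigma)
        out = inrf_oracle(blurred, params)
        # readout at the midpoint of the center segment; an even-width
        # segment has no single central sample, so average the middle two
        start = (cfg.total_width - cfg.center_width) // 2
        mid = start + cfg.center_width // 2
        if cfg.center_width % 2 == 0:
            resp = 0.5 * (out.values[mid - 1] + out.values[mid])
        else:
            resp = out.values[mid]
        v[i] = max(0.0, float(resp))
    return ResponseCurve(u=u_grid, v=v, bar_width=bar_width)


def response_transition(curve: ResponseCurve, zero_tol: float = 1e-9) -> float:
    """Center value at which the response switches between positive and zero.

    Returns the midpoint between the last grid point on one side of the
    switch and the first on the other; assumes a single transition.
    """
    active = curve.v > zero_tol
    if active.all() or (~active).all():
        raise ValueError("response curve has no transition")
    flips = np.nonzero(active[:-1] != active[1:])[0]
    i = flips[0]
    return float(0.5 * (curve.u[i] + curve.u[i + 1]))


# ---------------------------------------------------------------------------
# Crispening
# ---------------------------------------------------------------------------

CrispeningModel = Literal["inrf_b", "lnl_uniform_fit", "lnl_saltpepper_fit"]

_CRISPENING_MODELS = {
    "lnl_uniform_fit": LNL_UNIFORM_FIT,
    "lnl_saltpepper_fit": LNL_SALTPEPPER_FIT,
}


def _brightness_pipeline(display: Raster, model: CrispeningModel,
                         inrf_params: INRFParams, levels) -> np.ndarray:
    """Naka-Rushton (adaptive semisaturation) then the selected operator."""
    b_k = float(display.values.mean())
    S = crispening_semisaturation(b_k)
    I_k = naka_rushton(display, S=S, n=NAKA_RUSHTON_N)
    if model == "inrf_b":
        out = inrf_apply(I_k, inrf_params, levels=levels)
    else:
        out = lnl_apply(I_k, _CRISPENING_MODELS[model])
    return out.values


def run_crispening(model: CrispeningModel = "inrf_b",
                   uniform_levels: Sequence[float] = UNIFORM_BACKGROUNDS,
                   salt_pepper_fractions: Sequence[float] = SALT_PEPPER_FRACTIONS,
                   inrf_params: INRFParams = INRF_B,
                   seed: int = 0,
                   levels="auto") -> list[BrightnessCurve]:
    """Brightness curves for every requested background.

    Returns one :class:`BrightnessCurve` per uniform level and per
    salt-and-pepper black fraction, in that order.  Each curve samples the
    model output at the 11 circle centers of the display.
    """
    curves: list[BrightnessCurve] = []
    for kind, level_list in (("uniform", uniform_levels),
                             ("salt_pepper", salt_pepper_fractions)):
        for level in level_list:
            cfg = BrightnessDisplayConfig(background_kind=kind,
                                          background_level=float(level),
                                          seed=seed)
            display = make_brightness_display(cfg)
            out = _brightness_pipeline(display, model, inrf_params, levels)
            centers = display_circle_centers(cfg)
            samples = np.array([out[r, c] for r, c in centers])
            curves.append(BrightnessCurve(
                background_kind=kind,
                background_level=float(level),
                mean_luminance=float(display.values.mean()),
                circle_luminances=np.asarray(cfg.circle_luminances),
                outputs=samples,
            ))
    return curves


def slope_peak_statistic(curve: BrightnessCurve,
                         background_level: Optional[float] = None) -> Dict[str, float]:
    """Locate the brightness curve's steepest point.

    Finite-difference slopes (centered in the interior, one-sided at the
    ends) of output versus circle luminance; returns the luminance of the
    maximum slope and the ratio of that slope to the median slope (a
    peakedness measure: 1 for a straight line).
    """
    L, O = curve.circle_luminances, curve.outputs
    if len(L) < 3:
        raise ValueError("need at least 3 points")
    slopes = np.gradient(O, L)
    peak_idx = int(np.argmax(slopes))
    med = float(np.median(slopes))
    ratio = float(slopes[peak_idx] / med) if med > 0 else float("inf")
    result = {
        "peak_location": float(L[peak_idx]),
        "peak_ratio": ratio,
        "peak_slope": float(slopes[peak_idx]),
    }
    if background_level is not None:
        nearest = float(L[np.argmin(np.abs(L - background_level))])
        result["nearest_probe"] = nearest
        result["aligned"] = float(result["peak_location"] == nearest)
    return result


def local_crispening_index(curve: BrightnessCurve, background_level: float) -> float:
    """Background-local slope elevation of a brightness curve.

    Ratio of the slope of the probe segment that brackets (or abuts) the
    background level to the median slope of the remaining segments.  A
    value well above 1 means the curve steepens locally at the background
    — the crispening signature — independently of the overall curve shape
    (the photoreceptor stage alone makes brightness curves globally
    steepest at the dark end, which the global peak statistic picks up).
    """
    L, O = curve.circle_luminances, curve.outputs
    seg_slopes = np.diff(O) / np.diff(L)
    probe = int(np.argmin(np.abs(L - background_level)))
    # the kink sits at the probe nearest the background; examine the
    # segment(s) touching it
    adjacent = [k for k in (probe - 1, probe) if 0 <= k < len(seg_slopes)]
    peak = float(np.max(seg_slopes[adjacent]))
    others = np.delete(seg_slopes, adjacent)
    med = float(np.median(others))
    if med <= 0:
        return float("inf") if peak > 0 else float("nan")
    return float(peak / med)


# ---------------------------------------------------------------------------
# White's illusion under bandpass noise
# ---------------------------------------------------------------------------

def default_noise_freqs() -> np.ndarray:
    """Six log-spaced band centers, 0.5-9 cycles/degree."""
    return np.geomspace(0.5, 9.0, 6)


def _white_model_output(stim: Raster, params: INRFParams, gamma: float,
                        levels) -> np.ndarray:
    clipped = np.clip(stim.values, 0.0, 1.0)
    linear = power_law(clipped, gamma)
    out = inrf_apply(Raster(linear, pixels_per_degree=stim.pixels_per_degree),
                     params, levels=levels)
    return out.values


def white_strength_raw(stim_cfg: WhiteStimulusConfig,
                       params: INRFParams = WHITE_INRF, gamma: float = 2.2,
                       levels=32) -> float:
    """Signed patch difference: mean output on the black-bar patch minus
    mean output on the white-bar patch."""
    stim = make_white_stimulus(stim_cfg)
    out = _white_model_output(stim, params, gamma, levels)
    on_white, on_black = white_patch_masks(stim_cfg)
    return float(out[on_black].mean() - out[on_white].mean())


def run_white(noise_freqs: Optional[Sequence[float]] = None,
              n_real: int = 25, seed: int = 0,
              noise_rms: float = 0.1,
              params: INRFParams = WHITE_INRF, gamma: float = 2.2,
              levels=32) -> list[IllusionStrengthResult]:
    """Illusion strength per noise band, averaged over seeded realizations.

    The strength of one realization is the difference between the mean
    model outputs on the two test patches, signed so that the noise-free
    illusion's polarity counts as positive; results report mean and sd
    over ``n_real`` realizations per band.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    if noise_freqs is None:
        noise_freqs = default_noise_freqs()
    base = WhiteStimulusConfig()
    polarity = np.sign(white_strength_raw(base, params, gamma, levels))
    if polarity == 0:
        polarity = 1.0
    results = []
    ss_root = np.random.SeedSequence(seed)
    for band_idx, f0 in enumerate(noise_freqs):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(band_idx,))
        real_seeds = child.generate_state(n_real) % (2 ** 31)
        strengths = np.empty(n_real)
        for r in range(n_real):
            cfg = WhiteStimulusConfig(noise_center_cpd=float(f0),
                                      noise_rms=noise_rms,
                                      seed=int(real_seeds[r]))
            strengths[r] = polarity * white_strength_raw(cfg, params, gamma, levels)
        results.append(IllusionStrengthResult(
            center_freq_cpd=float(f0),
            mean_strength=float(strengths.mean()),
            sd=float(strengths.std(ddof=1)) if n_real > 1 else 0.0,
            n_realizations=n_real,
            strengths=strengths,
        ))
    return results


# ---------------------------------------------------------------------------
# Irradiation illusion
# ---------------------------------------------------------------------------

def apparent_width(profile: np.ndarray, polarity: str,
                   flank: int = 50) -> int:
    """Width of the perceived figure, by mid-threshold crossing.

    The threshold is the midpoint between the profile's central (figure)
    level and its far-field (ground) level; the apparent width counts the
    samples on the figure's side of that threshold.
    """
    inside = float(profile[len(profile) // 2])
    outside = float(np.mean(np.concatenate([profile[:flank], profile[-flank:]])))
    thr = 0.5 * (inside + outside)
    if polarity == "white_on_black":
        return int(np.sum(profile > thr))
    return int(np.sum(profile < thr))


def run_irradiation(params: INRFParams = IRRADIATION_INRF,
                    blur_sigma: float = 20.0,
                    nr_semisaturation: float = 0.18) -> IrradiationResult:
    """Blur, Naka-Rushton (n=1, S=0.18), INRF, clip to [0, 1], measure widths."""
    profiles: Dict[str, np.ndarray] = {}
    widths: Dict[str, int] = {}
    for polarity in ("white_on_black", "black_on_white"):
        stim = make_irradiation_signal(polarity)
        blurred = retinal_blur(stim, blur_sigma)
        receptor = naka_rushton(blurred, S=nr_semisaturation, n=1.0)
        out = inrf_oracle(receptor, params)
        clipped = np.clip(out.values, 0.0, 1.0)
        profiles[polarity] = clipped
        widths[polarity] = apparent_width(clipped, polarity)
    return IrradiationResult(profiles=profiles, widths=widths)
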