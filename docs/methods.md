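# Methods

## The operator

The INRF maps a 1D signal or 2D image `I` to

```
INRF(x) = Σᵢ m(x−yᵢ) I(yᵢ) − λ Σᵢ w(x−yᵢ) σ( I(yᵢ) − (g∗I)(x) )
```

with shift-invariant kernels `m`, `w`, `g`, a scalar balance `λ` and a
pointwise nonlinearity `σ` with `σ(0) = 0`.  The defining feature is that
`σ` is centered on a local average of the signal around the *output*
location, so the same neighbor is transformed differently depending on
which point it contributes to.  Consequences implemented and tested here:

- constant images are exact fixed points (normalized `m`, `g`, `σ(0)=0`);
- the operator is not homogeneous for power-law `σ` (no single
  convolution kernel reproduces it);
- it is translation-equivariant under periodic boundaries;
- with `σ(z) = αz` it reduces exactly to one kernel
  `k = m − λαw + λα(Σᵢwᵢ)g` (`reduce_to_linear`), which is
  center-positive / surround-negative for Gaussian `m`, `g` and a wider
  Gaussian `w`.

Only shift-invariant kernels are supported; the general position-dependent
form `m(x, yᵢ)` is out of scope because every concrete instantiation used
by the experiments is shift-invariant.

## Evaluators

`inrf_oracle` is the literal double loop over output locations and kernel
taps — the correctness reference, used directly by the 1D pipelines
(signals of 512–1024 samples).

`inrf_apply` is a level-decomposition evaluator in the spirit of
constant-time bilateral filtering.  With `c = g∗I`, the nonlinear term at
level value `c_l` is an ordinary convolution `T_l = w ∗ σ(I − c_l)`; the
operator output reads the stack `T` at `c(x)`.  If `c` takes at most
`levels` distinct values (the default budget is 64) the distinct values
are used and the result is *exact* — this covers every piecewise-constant
display in the experiments (uniform and salt-and-pepper brightness
displays have ≤ 13 distinct values after the photoreceptor stage).
Otherwise `levels` uniformly spaced values span `[min c, max c]` and the
read is linearly interpolated between the bracketing levels; on random
smooth images in [0,1] at the brightness-operator parameters the error
against the oracle is ≈ 5·10⁻⁴ at 64 levels (tested bound 10⁻³).  The
White's-illusion runs use 32 levels; the illusion strengths change by
< 10⁻³ against 64 levels while halving runtime.

Large convolutions go through an overlap-save circular FFT at the minimal
alias-free length with cached kernel transforms; small ones run directly.
Both honor the boundary policy exactly (verified against `scipy.ndimage`).
Everything is double precision.

Boundary policies: `mirror` (symmetric, edge-inclusive reflection — the
default; avoids edge darkening in brightness displays), `replicate`,
`periodic` (used by the equivariance tests) and `zero` (the convention of
convolutional layers; used by the network layer).  For the zero boundary
the level decomposition pads the σ-field with `σ(0 − c_l)` per level so it
matches the literal definition, in which out-of-grid neighbors contribute
`σ(0 − c(x))`.

Gaussian kernels are truncated at ±4σ and renormalized (< 10⁻⁴ mass
lost); even requested box extents round up to the next odd integer with a
warning, so the whole-signal constant kernel of the ON/OFF experiment (512
printed) realizes as 513 taps of 1/513 — a < 0.2 % change of a global
mean with no observable effect.

## Fixed parameter sets

| experiment | front end | m | w | g | λ | σ |
|---|---|---|---|---|---|---|
| ON/OFF cells | Gaussian blur σ=4 px | box 85 | constant, full signal | box 85 | 1000 | sin(πz) if \|z\|<0.5, sign(z)·sin²(πz) else |
| crispening | Naka–Rushton n=0.74, adaptive S | Gaussian 52 px | Gaussian 178 px | delta | 3.875 | z^0.625 / −\|z\|^0.775 |
| INRF-IQ | CIELAB L* | Gaussian 52 px | Gaussian 178 px | delta | 3.875 | same |
| White's illusion | power law γ=2.2 | Gaussian 54 px | Gaussian 183 px | delta | 3.875 | same |
| irradiation | blur σ=20; NR(v)=v/(v+0.18) | Gaussian 100 px | Gaussian 342 px | delta | 3.875 | same |

The asymmetric power σ uses `−|z|^q` on the negative branch (never a
fractional power of a negative number).  The sinusoidal σ is applied
literally at all amplitudes, including |z| > 1.5 where the experiments
never drive it.

The adaptive semisaturation is `S = 0.5·18 + 0.5·10^(0.63·log₁₀(b)+1)`
with `b` the stimulus mean luminance in cd/m²: half a fixed mid-gray
anchor, half a power-law function of the adapting level.

## Experiment pipelines and conventions

**ON/OFF** (1D, 512 samples in [0,1]): alternating black/white bars of
width `b` (white bar first), center segment of 64 samples at value `u`,
Gaussian blur σ=4, the fixed INRF above, half-wave rectification
(`max(0, ·)` — the printed description says only "rectified").  The
response is read at the midpoint of the center segment; since the segment
has even width the two central samples are averaged (reading a single
off-center sample biases the 85-tap local mean by half a sample and
shifts the measured transition by ≈ 0.04).  Bar widths per regime are not
printed; the package exposes `{128, 32, 8, 4}` with 128 as the
low-frequency (OFF) default and 8 as the high-frequency (ON) default —
at these widths the positive/zero transition falls at 0.525 and 0.495,
i.e. at the background average 0.5 within half a sweep step.

**Crispening** (2D, 1280×960 at 64 px/deg): eleven 64 px circles on the
horizontal meridian.  Eleven 1° circles with 1° gaps would span 1344 px
and overflow the 1280 px display, so the gap is reduced to 57 px, the
largest integer that fits.  Circle luminances are probed at 11 linearly
spaced values from display black (0.65 cd/m²) to white (75 cd/m²).
Backgrounds: uniform {0.65, 19.24, 37.83, 56.41, 75} cd/m², and
salt-and-pepper black fractions {0, ¼, ½, ¾, 1}, whose mean luminances
equal the uniform levels (the end fractions are degenerate — they *are*
the uniform white/black displays).  Pipeline: Naka–Rushton with adaptive
`S` from the image mean, then INRF-B (or the L+NL baseline), then the
output at the 11 circle centers.

Two statistics quantify crispening.  `slope_peak_statistic` locates the
global maximum of the finite-difference slopes (centered in the interior,
one-sided at the ends) and its ratio to the median slope.  Because the
Naka–Rushton derivative diverges at low luminance (at 0.65 cd/m² it is
≈ 8× its value at 38 cd/m² for S ≈ 58), the *global* slope maximum over
this probe grid always sits at the darkest segment, for every model and
background; at 7.4 cd/m² probe spacing the σ-kink divergence at the
background (local slope ∝ ΔL^−0.375) cannot overcome it — that would
require sub-0.5 cd spacing.  `local_crispening_index` therefore measures
the phenomenon where it lives: the steeper of the two probe segments
touching the background's nearest probe, divided by the median of the
remaining segment slopes.  For INRF-B this index is well above 1 on every
uniform background and near 1 on the matched salt-and-pepper background —
the dichotomy — because the delta-`g` operator compares each surround
*pixel* to the center (a bimodal surround provides no single reference
level), while the L+NL baseline's DoG first smooths the surround to its
mean and keeps crispening on noise, pinned at the luminance whose
photoreceptor response equals the *mean photoreceptor response* of the
bimodal background (≈ 17 cd/m² for a 37.8 cd/m² mean — the Jensen gap of
the saturating front end), not at the photometric mean.

The L+NL baseline is `m∗I − λσ(DoG∗I)` with printed fits (uniform:
DoG σ 30/60 px, λ=2, σ exponents 0.5/0.7; salt-and-pepper: 40/50 px,
λ=10, 0.9/0.9).  The printed description does not fix the DoG's center
polarity; with a center-positive DoG the curves *decrease* with circle
luminance, so the fits use the center-negative orientation (`dog_sign =
−1`), the only one consistent with a brightness model.

**White's illusion** (2D): 384×384 canvas at 64 px/deg, six vertical
64 px bars (white first), two test patches of identical gray 0.5, one bar
wide × 128 px tall, on bars 2 (white) and 5 (black).  The geometry, the
grating contrast, the noise rms and the band centers are package
conventions (the source experiment's exact stimuli are external): noise
is isotropic one-octave bandpass (annulus `f₀/√2 … f₀·√2`), zero mean,
rms 0.1 in [0,1] units; band centers default to 6 log-spaced values in
0.5–9 c/deg.  Pipeline per realization: add noise, clip to [0,1]
(a physical display cannot leave its range, and the power law needs
nonnegative input), apply `I^2.2` (the γ exponent is a config default;
the source text does not print it), then the INRF (no Naka–Rushton).
Strength = mean output on the black-bar patch minus the white-bar patch,
signed so the noise-free illusion is positive; mean and sd are taken over
25 seeded realizations per band (seeds are spawned per band and
realization from one root seed, so shorter runs are prefixes of longer
ones).

**Irradiation** (1D, 1024 samples): central 400-sample step in both
polarities; blur σ=20, `NR(v)=v/(v+0.18)`, the fixed INRF, clip to
[0,1].  "Apparent width" is a package convention (the source reports only
the percept): the count of samples on the figure's side of the midpoint
between the profile's central plateau and its far-field level.  The λ=0
control with an identity front end is exactly polarity-symmetric, so any
width difference comes from the nonlinear branch and the asymmetric
photoreceptor stage.

**INRF-IQ**: both sRGB images → CIELAB L* (D65 2° white, the sRGB
standard) → INRF-B (on the L* scale, 0–100; the RMSE is taken on the
operator's output scale as written) → RMSE.  A stacked two-stage variant
is exposed (`stacked=True`).  Full resolution, no downsampling.  The MOS
harness correlates `−score` with opinion scores and reports signed and
absolute Pearson r; external databases are adapted, not bundled, and no
correlation value is claimed here beyond what the synthetic tests
compute.

## The trainable layer

The network form shares one learnable kernel between `m` and `w` and
takes `g` as a delta, so per output channel

```
out = Σ_d k(d) · [ x(·+d) − λ σ( x(·+d) − x ) ]
```

— *linear in the kernel*.  Weight gradients are therefore exact
correlations of the upstream gradient with the bracketed feature map; the
implementation is plain numpy with analytic gradients (verified against
central finite differences to < 10⁻³ relative error), zero padding and
"same" output size, matching the convolution layers it replaces.  `λ` is
a fixed hyperparameter (≈ 1–2), not learned; `λ=0` makes the layer a
standard convolution, exactly.  The cross-channel wiring applies the
per-channel kernels to both the linear and the σ-difference term and sums
over input channels — a declared convention where the published
multi-channel detail is not available.  σ never needs a derivative with
respect to the weights, so the non-smooth power σ at 0 poses no training
problem.

`train_demo` is a desk-scale end-to-end check, not a benchmark: 8×8
blobs-vs-stripes images (equal mean level, pixel noise 0.1), one
1→4-channel 3×3 INRF layer, ReLU, global average pooling, a linear
2-class head, Adam on softmax cross-entropy, all gradients analytic.  At
200 samples/class and 20 epochs the seeded run reaches 0 % training
error.  Passing says the gradients drive learning; it says nothing about
large-scale image classification.

## What the synthetic data does and does not show

The stimulus generators reproduce the *published stimulus descriptions*
(bar geometry, display calibration 0.65–75 cd/m², salt-and-pepper pixel
draws, step widths) and are bitwise-reproducible from their configs.
They do not emulate optics beyond a Gaussian blur, temporal dynamics,
chromatic content, or observer noise; passing tests show that the fixed
operator reproduces the qualitative phenomena on these idealized
displays, not that it fits any individual observer's data.  External
image-quality databases are deliberately not bundled; the IQ tests
exercise metric axioms (identity, symmetry, monotonicity in distortion)
on synthetic images only.

## Numerical choices

- Double precision throughout the scientific path; the layer is also
  float64 (its tolerance contract, 10⁻⁵, is single-precision-friendly).
- Level budget 64 (`inrf_apply` default), 32 for the White runs; exact
  decomposition whenever the local-mean field has ≤ budget distinct
  values.
- λ is applied exactly as printed — no renormalization by kernel mass.
- Direct convolution below 3·10⁷ multiply-accumulates, FFT above.
- Ties in "nearest probe" resolve to the lower luminance (argmin).
- `inrf_apply` rejects `levels < 2`; realized kernels reject non-positive
  sizes and a DoG with narrow ≥ wide.

## Known limitations

- The exact bar widths, White's-illusion geometry/noise parameters and
  the power-law exponent are not printed in the source descriptions;
  package defaults are declared conventions (flagged above) and exposed
  in configs.
- The global slope-peak statistic does not isolate crispening on coarse
  linear probe grids (see above); use `local_crispening_index` for the
  background-local effect.
- Spatially varying σ and position-dependent kernels are out of scope.
- The multi-channel nonlinear wiring of the layer is a declared
  convention pending the published supplementary detail.
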