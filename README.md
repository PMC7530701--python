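# inrf — intrinsically nonlinear receptive fields

Classical vision models describe a neuron's spatial summation as a linear
receptive field (RF), optionally followed by a pointwise nonlinearity
(the "L+NL" standard model).  A number of robust psychophysical and
neurophysiological phenomena resist that description: V1 cells that flip
between OFF and ON behavior as stimulus spatial frequency changes,
brightness "crispening" that vanishes on salt-and-pepper surrounds,
White's illusion under bandpass noise.  The *intrinsically nonlinear
receptive field* (INRF) is a single-neuron summation model that predicts
all of these with one fixed set of parameters:

```
INRF(x) = Σᵢ mᵢ I(yᵢ) − λ Σᵢ wᵢ σ( I(yᵢ) − (g∗I)(x) )
```

A linear branch (kernel `m`) sums the input as usual; a nonlinear branch
(kernel `w`) passes each neighbor through a nonlinearity `σ` *shifted by a
local average* `(g∗I)(x)` of the signal around the output location.
Because `σ`'s argument depends on `x`, the operator is not
shift-invariant in the L+NL sense: expressing one output point with linear
filters needs `N + 2` convolutions on an `N`-pixel image.  With
`σ(z) = αz` it collapses to a single kernel
`k = m − λαw + λα(Σw)g`, which for Gaussian `m`, `g` and a wider Gaussian
`w` has the familiar center–surround (difference-of-Gaussians) structure.

This package is for vision scientists and image-processing researchers who
want a tested, reusable implementation of the operator and its desk-scale
experiments. It provides:

- `inrf.core` — the operator with a brute-force reference evaluator
  (`inrf_oracle`) and a fast level-decomposition evaluator (`inrf_apply`,
  exact on piecewise-constant stimuli), plus the comparison models
  (`lrf_apply`, `lnrf_apply`, `lnl_apply`) and the linear reduction.
- `inrf.experiments` — the four vision-science pipelines: ON/OFF polarity
  reversal, brightness crispening over uniform vs salt-and-pepper
  backgrounds, White's illusion under one-octave bandpass noise, and the
  irradiation illusion.
- `inrf.iq` — INRF-IQ, a full-reference image quality metric: the RMSE
  between the INRF-B (brightness operator) responses of the CIELAB
  lightness of the two images, with a correlation harness for
  mean-opinion-score tables (a TID2013 layout adapter is included; the
  dataset is not bundled).
- `inrf.layer` — a trainable multi-channel INRF layer with the shape
  contract of a 2D convolution (`m` and `w` share one learnable kernel,
  `g` is a delta, zero padding). The forward pass is linear in the kernel,
  so weight gradients are exact correlations — implemented in numpy with
  analytic gradients and verified against finite differences.
- `inrf.stimuli` — seeded, bitwise-reproducible generators for every
  synthetic stimulus the experiments need.

## Worked example

```python
import numpy as np
from inrf.experiments import run_onoff, response_transition, run_irradiation

low = run_onoff(bar_width=128)    # wide bars: low spatial frequency
high = run_onoff(bar_width=8)     # narrow bars: high spatial frequency
print("low-frequency transition :", response_transition(low))
print("high-frequency transition:", response_transition(high))
print("OFF at low freq :", low.v[20] > 0, low.v[80] == 0)   # u=0.2 / u=0.8
print("ON at high freq :", high.v[20] == 0, high.v[80] > 0)

irr = run_irradiation()
print("apparent widths:", irr.widths)
```

prints

```
low-frequency transition : 0.525
high-frequency transition: 0.495
OFF at low freq : True True
ON at high freq : True True
apparent widths: {'white_on_black': 444, 'black_on_white': 378}
```

One fixed operator (constant `m`, `g` of 85 samples, constant `w` over the
whole 512-sample signal, λ=1000, sinusoidal σ) responds only *below* the
mean level 0.5 for wide bars (an OFF cell) and only *above* it for narrow
bars (an ON cell); the transition sits at the background average in both
regimes.  In the irradiation experiment the white figure on black ground
produces a wider apparent profile (444 samples) than the physically equal
black-on-white figure (378), reproducing the classic illusion.

A CLI mirrors the library:

```bash
inrf onoff --b 128 --out out/onoff        # response_curve.csv + plot + manifest
inrf crispening --model inrf_b --out out/crisp
inrf white --n-real 25 --seed 1 --out out/white
inrf irradiation --out out/irr
inrf iq reference.png distorted.png
inrf selftest
```

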