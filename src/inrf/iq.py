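"""INRF-IQ: a full-reference image quality metric.

Both images are converted to CIELAB lightness (which plays the role of
the photoreceptor nonlinearity), passed through the fixed brightness
operator INRF-B, and compared by root mean square error::

    INRF-IQ(R, D) = RMSE(INRF-B(L*_R), INRF-B(L*_D))

The score is a pseudometric surrogate at the lightness level:
nonnegative, symmetric, zero for identical inputs.  Larger distortion
gives a larger score, so the correlation harness correlates ``-score``
with mean opinion scores (MOS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .core import INRFParams, Raster, inrf_apply
from .experiments import INRF_B
from .front_end import srgb_to_lightness

__all__ = ["IQResult", "MOSCorrelation", "inrf_iq", "evaluate_mos_correlation",
           "tid2013_table"]

logger = logging.getLogger("inrf")


@dataclass
class IQResult:
    """INRF-IQ score: RMSE between the two INRF-B outputs (>= 0)."""

    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be nonnegative")


def _load_srgb(img) -> np.ndarray:
    if isinstance(img, (str, Path)):
        import imageio.v3 as iio

        return np.asarray(iio.imread(img))
    return np.asarray(img)


def _inrf_b_response(arr: np.ndarray, params: INRFParams, levels,
                     stacked: bool) -> np.ndarray:
    L = srgb_to_lightness(arr) if arr.ndim == 3 else np.asarray(arr, dtype=float)
    out = inrf_apply(Raster(L, value_range=(0.0, 100.0)), params, levels=levels).values
    if stacked:
        out = inrf_apply(Raster(out, value_range=(0.0, 100.0)), params,
                         levels=levels).values
    return out


def inrf_iq(ref, dist, params: INRFParams = INRF_B, levels=64,
            stacked: bool = False) -> IQResult:
    """Score a distorted image against its reference.

    Accepts file paths or arrays; 3-channel inputs are taken as 8-bit sRGB
    and reduced to CIELAB lightness, 2D arrays are used as lightness
    directly.  ``stacked=True`` runs two INRF-B stages in sequence (the
    10-parameter variant).
    """
    a, b = _load_srgb(ref), _load_srgb(dist)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    Oa = _inrf_b_response(a, params, levels, stacked)
    Ob = _inrf_b_response(b, params, levels, stacked)
    return IQResult(score=float(np.sqrt(np.mean((Oa - Ob) ** 2))))


@dataclass
class MOSCorrelation:
    """Pearson correlation of -score with MOS over a pair table."""

    r: float
    abs_r: float
    n_used: int
    n_skipped: int


def evaluate_mos_correlation(pair_table: Iterable[Tuple], **iq_kwargs) -> MOSCorrelation:
    """Correlate the metric with mean opinion scores.

    ``pair_table`` holds ``(ref, dist, mos)`` rows (paths or arrays).
    Unreadable rows are skipped with a logged count; fewer than 3 valid
    rows or zero score variance is an error.
    """
    scores, mos = [], []
    skipped = 0
    for row in pair_table:
        ref, dist, m = row
        try:
            scores.append(inrf_iq(ref, dist, **iq_kwargs).score)
            mos.append(float(m))
        except (OSError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping pair %r: %s", row, exc)
    if skipped:
        logger.warning("skipped %d unreadable pairs", skipped)
    if len(scores) < 3:
        raise ValueError(f"need at least 3 valid pairs, got {len(scores)}")
    scores_arr = np.asarray(scores)
    if np.ptp(scores_arr) == 0:
        raise ValueError("scores have zero variance; correlation undefined")
    r = float(stats.pearsonr(-scores_arr, np.asarray(mos)).statistic)
    return MOSCorrelation(r=r, abs_r=abs(r), n_used=len(scores), n_skipped=skipped)


def tid2013_table(root: Union[str, Path],
                  mos_file: str = "mos_with_names.txt") -> list:
    """Adapter for the TID2013 directory layout.

    Reads ``<root>/mos_with_names.txt`` (``<mos> <distorted-name>`` rows;
    reference = ``reference_images/<ID>.BMP`` from the first token of the
    distorted name) and returns a ``(ref, dist, mos)`` table for
    :func:`evaluate_mos_correlation`.  The dataset itself is not bundled.
    """
    root = Path(root)
    table = []
    for line in (root / mos_file).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        mos_str, name = line.split(maxsplit=1)
        ref_id = name.split("_")[0].upper()
        table.append((
            root / "reference_images" / f"{ref_id}.BMP",
            root / "distorted_images" / name,
            float(mos_str),
        ))
    return table
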