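"""Shared parametric categorical-loudness surface family.

A listener's loudness surface maps (frequency, level) to categorical units
(CU) on the 0-10 scale that underlies the 11-category loudness scale
("Can't Hear" = 0 ... "Too Loud" = 10).  The family used throughout the
package -- by the synthetic-listener generator, by the Bayesian adaptive
(qCLS) engine's hypothesis grid, and by the profile fitter -- is:

    CU(f, L) = g(L - B * bump(f, L); T(f), s(f))

where

* ``g`` is a two-segment piecewise-linear growth function of level:
  CU = 0.5 at the threshold level ``T``, growing with a shallow slope
  (half the main slope) up to the knee at CU = 1.5, and with the main
  slope ``s`` (cat/dB) above the knee.  Clamped to [0, 10].
* ``T(f)`` and ``s(f)`` are interpolated piecewise-linearly in log2
  frequency (thresholds and slopes are specified at anchor or audiogram
  frequencies); outside the outer knots the edge segments extrapolate.
* ``bump(f, L)`` is a smooth unit-height Gaussian bump in
  (log2 frequency, level) describing the *shape* of the bandwidth-dependent
  equivalent-level offset (mid-bandwidth loudness depression); ``B`` (dB)
  scales it.  ``B = 0`` for pure tones.

Categorical responses are modeled as ``clamp(round(CU + eps), 0, 10)`` with
Gaussian ``eps``; the implied category probabilities are differences of
Gaussian CDFs (a discretized Gaussian), computed here in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

#: Anchor frequencies (Hz) of the compact 3-knot family used by the
#: adaptive procedure and the profile fitter.
ANCHOR_FREQS = (500.0, 1000.0, 4000.0)

#: CU value of the knee separating the shallow near-threshold segment from
#: the main growth segment.
KNEE_CU = 1.5

#: Slope below the knee, as a fraction of the main slope.
LOW_SLOPE_FRACTION = 0.5


@dataclass(frozen=True)
class BumpShape:
    """Shape of the bandwidth-offset bump (unit peak height).

    Defaults place the peak at 1 kHz and 60 dB SPL.  ``spread_level`` is
    calibrated so that, averaged over the category-boundary levels of a
    default normal-hearing listener at 1 kHz, a 7-dB-peak offset averages
    ~4.1 dB (the pooled-across-categories mixed-model contrast).
    """

    center_freq: float = 1000.0   # Hz
    center_level: float = 60.0    # dB SPL
    spread_logf: float = 1.0      # octaves (log2 units)
    spread_level: float = 25.4    # dB

    def __call__(self, freq, level):
        zf = np.log2(np.asarray(freq, dtype=float) / self.center_freq) / self.spread_logf
        zl = (np.asarray(level, dtype=float) - self.center_level) / self.spread_level
        return np.exp(-0.5 * (zf * zf + zl * zl))


DEFAULT_BUMP = BumpShape()


def interp_log2(freq, knot_freqs, knot_values, extrapolation: str = "linear"):
    """Piecewise-linear interpolation in log2(frequency).

    ``extrapolation='linear'`` continues the edge segments beyond the outer
    knots (this is what produces 8-kHz predictions from data limited to
    <= 6 kHz); ``'clamp'`` holds the edge values constant -- used for slope
    parameters, which must stay strictly positive.
    """
    x = np.log2(np.asarray(freq, dtype=float))
    xk = np.log2(np.asarray(knot_freqs, dtype=float))
    yk = np.asarray(knot_values, dtype=float)
    if xk.ndim != 1 or xk.size < 2:
        raise ValueError("need at least two knots")
    y = np.interp(x, xk, yk)
    if extrapolation == "linear":
        lo = x < xk[0]
        hi = x > xk[-1]
        if np.any(lo):
            slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
            y = np.where(lo, yk[0] + slope * (x - xk[0]), y)
        if np.any(hi):
            slope = (yk[-1] - yk[-2]) / (xk[-1] - xk[-2])
            y = np.where(hi, yk[-1] + slope * (x - xk[-1]), y)
    elif extrapolation != "clamp":
        raise ValueError("extrapolation must be 'linear' or 'clamp'")
    return y


def cu_growth(level, threshold, slope):
    """Two-segment piecewise-linear CU growth, clamped to [0, 10].

    CU = 0.5 at ``threshold`` (the "Can't Hear"/"Very Soft" crossing);
    slope ``LOW_SLOPE_FRACTION * slope`` up to the knee at CU = KNEE_CU,
    slope ``slope`` (cat/dB) above.  Vectorized over all arguments.
    """
    level = np.asarray(level, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    slope = np.asarray(slope, dtype=float)
    s0 = LOW_SLOPE_FRACTION * slope
    knee_level = threshold + (KNEE_CU - 0.5) / s0
    below = 0.5 + s0 * (level - threshold)
    above = KNEE_CU + slope * (level - knee_level)
    cu = np.where(level <= knee_level, below, above)
    return np.clip(cu, 0.0, 10.0)


def boundary_level(threshold, slope, k):
    """Level at which noiseless CU crosses k - 0.5 (k = 1..10), closed form."""
    k = np.asarray(k, dtype=float)
    s0 = LOW_SLOPE_FRACTION * np.asarray(slope, dtype=float)
    knee_level = threshold + (KNEE_CU - 0.5) / s0
    below = threshold + (k - 0.5 - 0.5) / s0
    above = knee_level + (k - 0.5 - KNEE_CU) / np.asarray(slope, dtype=float)
    return np.where(k - 0.5 <= KNEE_CU, below, above)


def surface_cu(freq, level, anchor_thresholds, anchor_slopes, bump_db=0.0,
               bump=DEFAULT_BUMP, anchor_freqs=ANCHOR_FREQS):
    """CU of the compact anchored family at (freq, level)."""
    t = interp_log2(freq, anchor_freqs, anchor_thresholds)
    s = interp_log2(freq, anchor_freqs, anchor_slopes)
    eff = np.asarray(level, dtype=float) - bump_db * bump(freq, level)
    return cu_growth(eff, t, s)


def category_probabilities(cu, response_sd):
    """Probabilities of the 11 response categories given expected CU.

    The response is ``clamp(round(cu + eps), 0, 10)`` with
    ``eps ~ N(0, response_sd)``; category ``c`` therefore has mass
    ``Phi((c + 0.5 - cu)/sd) - Phi((c - 0.5 - cu)/sd)`` with the tails
    absorbed into categories 0 and 10.  Returns an array with a trailing
    axis of length 11; sums to 1 exactly.
    """
    cu = np.asarray(cu, dtype=float)
    if response_sd <= 0:
        # degenerate limit: point mass on round(cu)
        cats = np.clip(np.round(cu), 0, 10).astype(int)
        out = np.zeros(cu.shape + (11,))
        np.put_along_axis(out, cats[..., None], 1.0, axis=-1)
        return out
    edges = np.arange(1, 11) - 0.5  # 0.5, 1.5, ..., 9.5
    z = (edges - cu[..., None]) / response_sd
    cdf = ndtr(z)
    lower = np.concatenate([np.zeros_like(cdf[..., :1]), cdf], axis=-1)
    upper = np.concatenate([cdf, np.ones_like(cdf[..., :1])], axis=-1)
    return upper - lower


def category_probability(cu, response_sd, category: int):
    """Mass of a single response category (vectorized over ``cu``)."""
    cu = np.asarray(cu, dtype=float)
    if response_sd <= 0:
        return (np.clip(np.round(cu), 0, 10) == category).astype(float)
    upper = (ndtr((category + 0.5 - cu) / response_sd)
             if category < 10 else np.ones_like(cu))
    lower = (ndtr((category - 0.5 - cu) / response_sd)
             if category > 0 else np.zeros_like(cu))
    return upper - lower


def category_entropy(cu, response_sd):
    """Shannon entropy (nats) of the 11-category response distribution."""
    p = category_probabilities(cu, response_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return -t.sum(axis=-1)
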