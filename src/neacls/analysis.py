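"""Group-level statistics of fitted loudness profiles.

Covers the derived quantities of the study: loudness-growth slopes
(cat/dB), mid-bandwidth loudness reduction and spectral loudness summation
(equally-loud-tone level differences), equal-loudness-contour summaries
(loudness loss and hearing-aid gain), the linear mixed-effects model of
category-boundary levels, and the independent-samples t-test on slopes.

Loudness functions are inverted by piecewise-linear interpolation between
the 10 fitted category boundaries (CU = k - 0.5 at boundary k), with edge
segments extended linearly when a query falls outside the fitted range
(flagged by a warning).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedSlopeError
from .profiles import PROFILE_FREQS, LoudnessProfile

_BOUNDARY_CU = np.arange(1, 11) - 0.5  # CU at boundaries 1..10


def _interp_extrap(x, xp, yp):
    """np.interp with linear extension beyond the end points."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, yp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        y = np.where(lo, yp[0] + (x - xp[0]) * (yp[1] - yp[0]) / (xp[1] - xp[0]), y)
    if np.any(hi):
        y = np.where(
            hi, yp[-1] + (x - xp[-1]) * (yp[-1] - yp[-2]) / (xp[-1] - xp[-2]), y
        )
    return y


def loudness_at(profile: LoudnessProfile, freq: float, level) -> np.ndarray:
    """Expected CU at (freq, level), interpolated from the boundary levels."""
    b = profile.boundary_at(freq)
    level = np.asarray(level, dtype=float)
    if np.any((level < b[0]) | (level > b[-1])):
        warnings.warn("level outside the fitted dynamic range; extrapolating",
                      RuntimeWarning)
    return _interp_extrap(level, b, _BOUNDARY_CU)


def level_at(profile: LoudnessProfile, freq: float, cu) -> np.ndarray:
    """Level (dB SPL) at which the profile reaches the given CU."""
    b = profile.boundary_at(freq)
    return _interp_extrap(np.asarray(cu, dtype=float), _BOUNDARY_CU, b)


def loudness_slope(profile: LoudnessProfile, freq: float,
                   boundaries=range(2, 10), max_level: float | None = None
                   ) -> float:
    """Least-squares loudness-growth slope (cat/dB) at one frequency.

    Regresses boundary CU on boundary level using boundaries 2-9 by
    default (the extremes are excluded to avoid floor/ceiling distortion).
    ``max_level`` optionally restricts the regression to boundary levels
    below a cutoff (e.g. 80 dB SPL).
    """
    ks = np.asarray(list(boundaries), dtype=int)
    levels = profile.boundary_at(freq)[ks - 1]
    cu = ks - 0.5
    if max_level is not None:
        keep = levels < max_level
        levels, cu = levels[keep], cu[keep]
    if len(levels) < 2:
        raise UndefinedSlopeError("need at least two boundaries for a slope")
    if np.ptp(levels) < 1e-9:
        raise UndefinedSlopeError("boundary levels are degenerate (equal)")
    return float(stats.linregress(levels, cu).slope)


def loudness_reduction(profile_tone: LoudnessProfile,
                       profile_narrow: LoudnessProfile,
                       freq: float, level: float) -> float:
    """Mid-bandwidth loudness reduction in dB at (freq, level).

    The narrow-band stimulus at ``level`` is as loud as a tone at some
    (lower) level; the reduction is ``level`` minus that equally-loud tone
    level, so positive values mean the narrow-band sound is softer than an
    equal-SPL tone.
    """
    cu = loudness_at(profile_narrow, freq, level)
    tone_level = level_at(profile_tone, freq, cu)
    return float(level - tone_level)


def loudness_summation(profile_quarter: LoudnessProfile,
                       profile_octave: LoudnessProfile,
                       freq: float, level: float) -> float:
    """Spectral loudness summation in dB at (freq, level): the change when
    one-octave noise is compared to quarter-octave noise at the same level
    (positive = octave noise louder)."""
    cu = loudness_at(profile_quarter, freq, level)
    quarter_level = level_at(profile_octave, freq, cu)
    return float(level - quarter_level)


# ---------------------------------------------------------------------------
# boundary tables and the mixed model


def boundary_table(profiles, freqs=None) -> pd.DataFrame:
    """Long-format table of boundary levels.

    ``profiles`` is an iterable of (group, LoudnessProfile) or of profiles
    whose ``listener_id`` starts with the group name.  One row per
    (participant, bandwidth, boundary, frequency).
    """
    rows = []
    freqs = PROFILE_FREQS if freqs is None else np.atleast_1d(freqs)
    for item in profiles:
        if isinstance(item, tuple):
            group, prof = item
        else:
            prof = item
            group = "HL" if prof.listener_id.startswith("HL") else "NH"
        for f in freqs:
            levels = prof.boundary_at(float(f))
            for k in range(1, 11):
                rows.append(
                    {
                        "participant": prof.listener_id,
                        "group": group,
                        "bandwidth": _bandwidth_label(prof.bandwidth_oct),
                        "category": k,
                        "freq": float(f),
                        "level": float(levels[k - 1]),
                    }
                )
    return pd.DataFrame(rows)


def _bandwidth_label(bandwidth_oct: float) -> str:
    if bandwidth_oct == 0:
        return "tone"
    if np.isclose(bandwidth_oct, 0.25):
        return "quarter"
    if np.isclose(bandwidth_oct, 1.0):
        return "octave"
    return f"{bandwidth_oct:g}oct"


def group_lmm(table: pd.DataFrame):
    """REML linear mixed model of boundary levels.

    ``level ~ C(group) * C(bandwidth) * C(category)`` with a random
    intercept per participant, fitted by REML (statsmodels MixedLM).
    Returns a dict with the fitted result, Type-III-style Wald F tests for
    each fixed-effect term (large-sample denominator df), and the NH
    quarter-octave-vs-tone contrast pooled across category boundaries.
    """
    import statsmodels.formula.api as smf

    for col, need in (("group", 2), ("bandwidth", 1), ("category", 1)):
        if table[col].nunique() < need:
            raise ValueError(f"table needs at least {need} levels of {col}")
    counts = table.groupby("group")["participant"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 participants per group")

    # sum-to-zero coding so joint Wald tests of interaction terms are
    # averaged over the other factors (Type III)
    formula = "level ~ C(group, Sum) * C(bandwidth, Sum) * C(category, Sum)"
    model = smf.mixedlm(formula, data=table, groups=table["participant"])
    fit = model.fit(reml=True)

    # Wald tests per fixed-effect term (joint test of the term's columns)
    terms = {}
    names = np.asarray(model.exog_names)
    term_of = _term_assignment(names)
    k_fe = len(names)
    for term in sorted(set(term_of.values())):
        if term == "Intercept":
            continue
        cols = [i for i, n in enumerate(names) if term_of[n] == term]
        contrast = np.zeros((len(cols), len(fit.params)))
        for r, c in enumerate(cols):
            contrast[r, c] = 1.0
        wt = fit.wald_test(contrast, scalar=False)
        stat = float(np.squeeze(wt.statistic)) / len(cols)
        df_num = len(cols)
        df_den = len(table) - k_fe
        p = 1.0 - stats.f.cdf(stat, df_num, df_den)
        terms[term] = {"F": stat, "df_num": df_num, "df_den": df_den, "p": float(p)}

    contrast_info = _nh_quarter_vs_tone_contrast(model, fit, table)
    return {
        "result": fit,
        "type3": terms,
        "nh_quarter_vs_tone_db": contrast_info["estimate"],
        "nh_quarter_vs_tone_se": contrast_info["se"],
        "converged": bool(fit.converged),
    }


def _term_assignment(names) -> dict:
    out = {}
    for n in names:
        if n == "Intercept":
            out[n] = "Intercept"
            continue
        # strip the bracketed factor levels to get the term id
        parts = n.split(":")
        term = ":".join(p.split("[")[0] for p in parts)
        term = term.replace("C(", "").replace(", Sum)", "").replace(")", "")
        out[n] = term
    return out


def _nh_quarter_vs_tone_contrast(model, fit, table) -> dict:
    """NH quarter-vs-tone boundary-level difference pooled over categories,
    as a linear contrast of the fixed effects."""
    import patsy

    cats = sorted(table["category"].unique())
    design = model.data.design_info if hasattr(model.data, "design_info") else None
    rows_q = pd.DataFrame(
        {"group": "NH", "bandwidth": "quarter", "category": cats}
    )
    rows_t = pd.DataFrame({"group": "NH", "bandwidth": "tone", "category": cats})
    di = getattr(model.data, "design_info", None)
    if di is None:
        di = patsy.dmatrix(
            "C(group, Sum) * C(bandwidth, Sum) * C(category, Sum)",
            table, return_type="dataframe",
        ).design_info
    xq = np.asarray(patsy.build_design_matrices([di], rows_q)[0])
    xt = np.asarray(patsy.build_design_matrices([di], rows_t)[0])
    c = (xq - xt).mean(axis=0)
    beta = fit.fe_params.values
    est = float(c @ beta)
    cov = fit.cov_params().values[: len(beta), : len(beta)]
    se = float(np.sqrt(c @ cov @ c))
    return {"estimate": est, "se": se}


def slope_ttest(slopes_nh, slopes_hl):
    """Independent-samples t-test on loudness-growth slopes.

    Returns (t, df, p) with the classic pooled-variance df = n1 + n2 - 2.
    """
    a = np.asarray(slopes_nh, dtype=float)
    b = np.asarray(slopes_hl, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(len(a) + len(b) - 2), float(p)


# ---------------------------------------------------------------------------
# cohort ELC summaries


def median_profile(profiles) -> np.ndarray:
    """Element-wise median boundary matrix across profiles (10 x 10)."""
    return np.median(np.stack([p.boundaries for p in profiles]), axis=0)


def mean_profile(profiles) -> np.ndarray:
    return np.mean(np.stack([p.boundaries for p in profiles]), axis=0)


def loudness_loss(hl_profiles, nh_profiles) -> pd.DataFrame:
    """Median HL equal-loudness contours minus mean NH contours (dB),
    per category boundary and frequency."""
    med_hl = median_profile(hl_profiles)
    avg_nh = mean_profile(nh_profiles)
    loss = med_hl - avg_nh
    out = pd.DataFrame(loss, columns=[f"{f:g}" for f in PROFILE_FREQS])
    out.insert(0, "category", np.arange(1, 11))
    return out


def hearing_aid_gain(nh_profiles, hl_profiles, freq: float,
                     levels=None) -> pd.DataFrame:
    """Gain (dB) required to restore normal loudness at each input level.

    For an input level L, the gain is the level at which the median HL
    loudness function reaches the mean NH loudness at L, minus L.  For
    recruiting (steeper) HL growth the gain shrinks with level.
    """
    j = int(np.argmin(np.abs(PROFILE_FREQS - freq)))
    nh = mean_profile(nh_profiles)[:, j]
    hl = median_profile(hl_profiles)[:, j]
    if levels is None:
        levels = np.arange(0.0, 101.0, 5.0)
    cu_nh = _interp_extrap(levels, nh, _BOUNDARY_CU)
    hl_level = _interp_extrap(cu_nh, _BOUNDARY_CU, hl)
    return pd.DataFrame(
        {"level": levels, "gain_db": hl_level - np.asarray(levels, dtype=float)}
    )
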