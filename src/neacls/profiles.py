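"""Loudness-profile fitting: from trial records to category-boundary levels.

A loudness profile is the 10 x 10 matrix of category-boundary levels (the
10 boundaries separating the 11 response categories, at the 10 standard
frequencies 0.25-8 kHz).  It is obtained by a maximum-a-posteriori fit of
the same parametric surface family the adaptive procedure uses --
thresholds and slopes at the three anchor frequencies plus (for noise
conditions) the bandwidth-offset amplitude -- followed by reading off, at
each frequency, the level where the expected CU crosses k - 0.5.

Although 8 kHz is never sampled, the cross-frequency structure of the
family extrapolates the surface there; the 8-kHz column is flagged as an
extrapolation in the fit diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._surface import (
    ANCHOR_FREQS,
    DEFAULT_BUMP,
    category_probabilities,
    cu_growth,
    interp_log2,
)
from .errors import TooFewTrialsError
from .qcls import DEFAULT_CONFIG, QclsConfig, QclsEngine, QclsRun, get_engine

#: Output frequencies of a loudness profile (Hz).
PROFILE_FREQS = np.array(
    [250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0, 6000.0, 8000.0]
)


@dataclass
class LoudnessProfile:
    """Fitted category-boundary levels.

    ``boundaries[k-1, j]`` is the level (dB SPL) of boundary k (the
    CU = k - 0.5 crossing) at ``PROFILE_FREQS[j]``; strictly increasing in
    k at every frequency.
    """

    boundaries: np.ndarray              # (10, 10) dB SPL
    stim_type: str = "tone"
    bandwidth_oct: float = 0.0
    listener_id: str = ""
    params: dict = field(default_factory=dict)
    fit_diagnostics: dict = field(default_factory=dict)

    @property
    def freqs(self) -> np.ndarray:
        return PROFILE_FREQS

    def boundary_at(self, freq: float) -> np.ndarray:
        """Boundary levels at one of the profile frequencies."""
        j = int(np.argmin(np.abs(PROFILE_FREQS - freq)))
        if not np.isclose(PROFILE_FREQS[j], freq):
            raise ValueError(f"{freq} Hz is not a profile frequency")
        return self.boundaries[:, j]


def _surface_cu(theta, freqs, levels, bandwidth_oct, bump):
    """CU of the 5-parameter family (anchor thresholds, shared slope, bump
    amplitude) at paired (freq, level) points."""
    t = interp_log2(freqs, ANCHOR_FREQS, theta[:3])
    s = theta[3]
    b = theta[4] if bandwidth_oct > 0 else 0.0
    eff = levels - b * bump(freqs, levels)
    return cu_growth(eff, t, s)


def _neg_log_posterior(theta, freqs, levels, cats, bandwidth_oct, bump,
                       response_sd, floor):
    from scipy.special import ndtr

    u = _surface_cu(theta, freqs, levels, bandwidth_oct, bump)
    upper = np.where(cats < 10, ndtr((cats + 0.5 - u) / response_sd), 1.0)
    lower = np.where(cats > 0, ndtr((cats - 0.5 - u) / response_sd), 0.0)
    nll = -np.log(np.maximum(upper - lower, floor)).sum()
    # weak ridge on the bump amplitude keeps the tone/noise families nested
    if bandwidth_oct > 0:
        nll += 1e-3 * theta[4] ** 2
    return nll


def fit_profile(trials, config: QclsConfig = DEFAULT_CONFIG,
                bandwidth_oct: float | None = None,
                listener_id: str = "", stim_type: str | None = None,
                engine: QclsEngine | None = None,
                init: np.ndarray | None = None) -> LoudnessProfile:
    """Maximum-a-posteriori surface fit to a qCLS trial record.

    ``trials`` is a list of TrialRecord or a QclsRun.  Requires at least 20
    trials spanning at least two frequencies.  The continuous optimization
    is initialized from a coarse evaluation on the adaptive procedure's own
    hypothesis grid (its MAP member) and refined by L-BFGS-B.
    """
    posterior = None
    if isinstance(trials, QclsRun):
        run = trials
        posterior = run.posterior
        if engine is None:
            engine = run.engine
        trials = run.trials
        listener_id = listener_id or run.listener_id
        stim_type = stim_type or run.condition
        if bandwidth_oct is None:
            bandwidth_oct = engine.bandwidth_oct if engine else None
    if bandwidth_oct is None:
        bandwidth_oct = trials[0].bandwidth_oct if trials else 0.0

    freqs = np.array([t.freq for t in trials], dtype=float)
    levels = np.array([t.level for t in trials], dtype=float)
    cats = np.array([t.category for t in trials], dtype=int)
    if len(trials) < 20:
        raise TooFewTrialsError(f"need >= 20 trials, got {len(trials)}")
    if np.unique(freqs).size < 2:
        raise TooFewTrialsError("trials must span at least two frequencies")

    bump = DEFAULT_BUMP
    sd = config.response_sd
    floor = config.likelihood_floor

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    else:
        if engine is None:
            engine = get_engine(config, bandwidth_oct)
        if posterior is not None:
            w = posterior.mass
            g = int(np.argmax(w))
            mean = np.concatenate([
                w @ engine.thresholds, [w @ engine.slopes], [w @ engine.bumps]
            ])
            mode = np.concatenate(
                [engine.thresholds[g], [engine.slopes[g]], [engine.bumps[g]]]
            )
            starts.extend([mean, mode])
        else:
            # coarse grid scan for the starting point
            ll = np.zeros(engine.n_hypotheses)
            for f in np.unique(freqs):
                m = freqs == f
                for lv in np.unique(levels[m]):
                    mm = m & (levels == lv)
                    u = engine.cu_at(float(f), float(lv))
                    p = category_probabilities(u, sd)
                    for c in cats[mm]:
                        ll += np.log(np.maximum(p[:, c], floor))
            g = int(np.argmax(ll))
            starts.append(np.concatenate(
                [engine.thresholds[g], [engine.slopes[g]], [engine.bumps[g]]]
            ))
        if bandwidth_oct > 0:
            # the bump amplitude has a shallow likelihood; restart around it
            for b0 in (0.0, 4.0, 8.0):
                s0 = starts[0].copy()
                s0[4] = b0
                starts.append(s0)

    bounds = [(-30.0, 100.0)] * 3 + [(0.02, 0.30)] + [(0.0, 15.0)]
    args = (freqs, levels, cats, bandwidth_oct, bump, sd, floor)
    res = None
    for s0 in starts:
        r = minimize(_neg_log_posterior, s0, args=args,
                     method="L-BFGS-B", bounds=bounds)
        if res is None or r.fun < res.fun:
            res = r
    theta = res.x

    boundaries = _boundaries_from_theta(theta, bandwidth_oct, bump)
    boundaries, projected = _ensure_monotone(boundaries)
    if projected:
        warnings.warn(
            "fitted surface produced non-monotone boundaries; projected onto "
            "the monotone cone", RuntimeWarning,
        )
    return LoudnessProfile(
        boundaries=boundaries,
        stim_type=stim_type or ("tone" if bandwidth_oct == 0 else "band_noise"),
        bandwidth_oct=float(bandwidth_oct),
        listener_id=listener_id,
        params={
            "anchor_freqs": list(ANCHOR_FREQS),
            "anchor_thresholds": theta[:3].tolist(),
            "slope": float(theta[3]),
            "bump_db": float(theta[4]) if bandwidth_oct > 0 else 0.0,
        },
        fit_diagnostics={
            "log_likelihood": float(-res.fun),
            "n_trials": int(len(trials)),
            "converged": bool(res.success),
            "extrapolated_freqs": [8000.0],
        },
    )


def _boundaries_from_theta(theta, bandwidth_oct, bump) -> np.ndarray:
    """Solve CU(f, L) = k - 0.5 for each boundary k and profile frequency
    by bisection (the surface is monotone in level)."""
    ks = np.arange(1, 11, dtype=float)
    lo = np.full((10, PROFILE_FREQS.size), -80.0)
    hi = np.full((10, PROFILE_FREQS.size), 200.0)
    target = (ks - 0.5)[:, None]
    ff = np.broadcast_to(PROFILE_FREQS, (10, PROFILE_FREQS.size))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = _surface_cu(theta, ff.ravel(), mid.ravel(), bandwidth_oct, bump)
        val = val.reshape(10, PROFILE_FREQS.size)
        lo = np.where(val < target, mid, lo)
        hi = np.where(val < target, hi, mid)
    return 0.5 * (lo + hi)


def _ensure_monotone(boundaries: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project each frequency column onto strictly-increasing levels."""
    out = boundaries.copy()
    projected = False
    for j in range(out.shape[1]):
        col = out[:, j]
        fixed = np.maximum.accumulate(col)
        if np.any(fixed != col) or np.any(np.diff(fixed) <= 0):
            projected = projected or np.any(fixed != col)
            # enforce strict increase with a minimal epsilon
            for k in range(1, len(fixed)):
                if fixed[k] <= fixed[k - 1]:
                    fixed[k] = fixed[k - 1] + 1e-6
        out[:, j] = fixed
    return out, projected


def elc(profile: LoudnessProfile, category_boundary: int) -> np.ndarray:
    """Equal-loudness contour: boundary levels across frequency for one
    category boundary (1..10).  Units dB SPL."""
    if not 1 <= category_boundary <= 10:
        raise ValueError("category boundary must be in 1..10")
    return profile.boundaries[category_boundary - 1, :]
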