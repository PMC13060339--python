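"""Bayesian adaptive categorical loudness scaling (qCLS).

The procedure maintains a posterior over a discretized grid of
loudness-surface hypotheses -- thresholds and slopes at three anchor
frequencies (0.5, 1, 4 kHz), interpolated in log frequency between them
(the "correlated loudness surface" assumption that lets a single run
cover the whole frequency range), plus, for noise conditions, the
amplitude of the bandwidth-dependent equivalent-level offset bump.

Before every trial the procedure picks the (frequency, level) pair on a
candidate lattice that maximizes the expected information gain about the
hypothesis, i.e. the mutual information between the categorical response
and the hypothesis, which equals the expected reduction in posterior
entropy.  After the response the posterior is updated multiplicatively
(Bayes rule) with a floored likelihood for robustness against lapses.

Two selection paths are provided: an exact computation, and a fast default
that quantizes each hypothesis's predicted CU into bins so the per-trial
cost is a single sparse matrix-vector product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from ._surface import (
    ANCHOR_FREQS,
    DEFAULT_BUMP,
    category_entropy,
    category_probabilities,
    category_probability,
    cu_growth,
    interp_log2,
)
from .errors import InvalidConfigError
from .listeners import ListenerModel
from .stimuli import StimType, StimulusSpec

#: Map from condition name to (stimulus type, bandwidth in octaves).
CONDITIONS = {
    "tone": (StimType.TONE, 0.0),
    "quarter": (StimType.BAND_NOISE, 0.25),
    "octave": (StimType.BAND_NOISE, 1.0),
}


@dataclass(frozen=True)
class QclsConfig:
    """Grid, lattice and response-model settings of the adaptive procedure.

    The candidate lattice spans 0.25-6 kHz (8 kHz is never sampled) in
    2-dB level steps over 0-100 dB SPL.
    """

    candidate_freqs: tuple = (250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0,
                              3000.0, 4000.0, 6000.0)
    level_min: float = 0.0
    level_max: float = 100.0
    level_step: float = 2.0
    threshold_grid: tuple = (0.0, 7.5, 15.0, 22.5, 30.0, 37.5, 45.0, 52.5, 60.0)  # dB SPL per anchor
    slope_grid: tuple = (0.07, 0.09, 0.11, 0.13, 0.15, 0.17)  # cat/dB, shared
    bump_grid: tuple = (0.0, 2.5, 5.0, 7.5, 10.0)           # dB (noise conditions)
    response_sd: float = 0.8                                # CU
    likelihood_floor: float = 1e-6
    n_trials: int = 100
    n_u_bins: int = 256                                     # fast-selection quantization
    # mid-run grid refinement: after this many trials the hypothesis grid
    # is rebuilt finely around the posterior mode and the trial history is
    # replayed (0 disables).  Refinement restores within-cell threshold
    # resolution, which keeps low levels informative and makes the bump
    # amplitude separable from the thresholds.
    refine_after: int = 50
    refine_threshold_span: float = 9.0                      # dB, +/- around mode
    refine_threshold_step: float = 3.0                      # dB
    refine_slope_span: float = 0.02                         # cat/dB
    refine_slope_step: float = 0.01
    refine_bump_grid: tuple = (0.0, 1.25, 2.5, 3.75, 5.0, 6.25, 7.5,
                               8.75, 10.0)

    def __post_init__(self):
        if not self.candidate_freqs or not self.threshold_grid or not self.slope_grid:
            raise InvalidConfigError("grids and lattice must be non-empty")
        if self.level_max < self.level_min:
            raise InvalidConfigError("level_max must be >= level_min")


DEFAULT_CONFIG = QclsConfig()


@dataclass
class TrialRecord:
    index: int              # 1-based trial number
    freq: float             # Hz
    level: float            # dB SPL
    bandwidth_oct: float
    category: int           # 0..10


@dataclass
class Posterior:
    """Belief state over the hypothesis grid."""

    log_mass: np.ndarray
    trial_count: int = 0

    @property
    def mass(self) -> np.ndarray:
        return np.exp(self.log_mass)

    def entropy(self) -> float:
        w = self.mass
        nz = w > 0
        return float(-(w[nz] * np.log(w[nz])).sum())

    def mode_index(self) -> int:
        return int(np.argmax(self.log_mass))


class QclsEngine:
    """Precomputed hypothesis grid and candidate lattice for one condition.

    Everything that does not depend on the listener (hypothesis CU values
    at every lattice candidate, their quantization, per-bin category
    probabilities and response entropies) is computed once and shared
    across listeners.
    """

    def __init__(self, config: QclsConfig = DEFAULT_CONFIG,
                 bandwidth_oct: float = 0.0, bump=DEFAULT_BUMP,
                 grids: dict | None = None, transient: bool = False):
        self.config = config
        self.bandwidth_oct = float(bandwidth_oct)
        self.bump = bump
        #: transient engines (mid-run refinements) never materialize the
        #: sparse histogram matrix; they fall back to direct bincounts
        self.transient = transient

        if grids is None:
            t_grids = (config.threshold_grid,) * 3
            slope_grid = config.slope_grid
            bump_grid = config.bump_grid if bandwidth_oct > 0 else (0.0,)
        else:
            t_grids = grids["thresholds"]
            slope_grid = grids["slopes"]
            bump_grid = grids["bumps"] if bandwidth_oct > 0 else (0.0,)
        # thresholds vary per anchor (audiogram tilts); the growth slope is
        # shared across frequency, which keeps the bandwidth-offset bump
        # identifiable from the off-peak frequencies
        hyp = list(product(t_grids[0], t_grids[1], t_grids[2],
                           slope_grid, bump_grid))
        self.thresholds = np.array([h[:3] for h in hyp], dtype=float)
        self.slopes = np.array([h[3] for h in hyp], dtype=float)
        self.bumps = np.array([h[4] for h in hyp], dtype=float)
        self.n_hypotheses = len(hyp)

        levels = np.arange(config.level_min, config.level_max + 1e-9, config.level_step)
        cand = [(lv, f) for lv in levels for f in sorted(config.candidate_freqs)]
        self.cand_levels = np.array([c[0] for c in cand])
        self.cand_freqs = np.array([c[1] for c in cand])
        self.n_candidates = len(cand)

        # CU of every hypothesis at every candidate
        u = self._cu_matrix(self.cand_freqs, self.cand_levels)

        # quantization for the fast selection path (uniform bins over the
        # 0-10 CU range)
        K = config.n_u_bins
        centers = (np.arange(K) + 0.5) * (10.0 / K)
        self._bin_p = category_probabilities(centers, config.response_sd)   # (K, 11)
        self._bin_h = category_entropy(centers, config.response_sd)         # (K,)
        idx = np.clip((u * (K / 10.0)).astype(np.int32), 0, K - 1)
        # bin index offset by candidate: histogramming the posterior mass
        # over (candidate, CU-bin) cells is one bincount / sparse matvec
        self._flat_idx = idx + (np.arange(self.n_candidates, dtype=np.int32)[None, :] * K)
        self._S = None   # built lazily: only broad posteriors need it
        self._K = K
        # the dense CU matrix is only kept on small grids (used by tests
        # and exact-mode diagnostics); large ones would dominate memory
        self.u = (u.astype(np.float32)
                  if u.size <= 5_000_000 else None)

    @property
    def _sparse_hist(self):
        if self._S is None:
            cols = np.repeat(np.arange(self.n_hypotheses), self.n_candidates)
            self._S = sparse.csr_matrix(
                (np.ones(self._flat_idx.size, dtype=np.float32),
                 (self._flat_idx.ravel(), cols)),
                shape=(self.n_candidates * self._K, self.n_hypotheses),
            )
        return self._S

    # -- hypothesis-surface evaluation ---------------------------------

    def _freq_coefs(self, freq, extrapolation: str = "linear") -> np.ndarray:
        """Coefficients expressing the log-f interpolation at ``freq`` as a
        linear combination of the three anchor values."""
        eye = np.eye(3)
        return np.array([
            interp_log2(freq, ANCHOR_FREQS, eye[i], extrapolation=extrapolation)
            for i in range(3)
        ])

    def cu_at(self, freq: float, level) -> np.ndarray:
        """CU of all hypotheses at one frequency and one or more levels."""
        t = self.thresholds @ self._freq_coefs(freq)
        s = self.slopes
        level = np.asarray(level, dtype=float)
        # effective level: subtract the hypothesis bump amplitude times the
        # unit bump evaluated at (freq, level)
        eff = level - self.bumps * np.asarray(self.bump(freq, level))
        return cu_growth(eff, t, s)

    def _cu_matrix(self, freqs, levels) -> np.ndarray:
        """CU of every hypothesis at paired (freq, level) points, grouped
        by frequency so the growth evaluation is fully vectorized."""
        out = np.empty((self.n_hypotheses, len(freqs)))
        for f in np.unique(freqs):
            cols = np.flatnonzero(freqs == f)
            t = self.thresholds @ self._freq_coefs(float(f))
            lv = levels[cols]
            eff = lv[None, :] - self.bumps[:, None] * np.asarray(
                self.bump(float(f), lv))[None, :]
            out[:, cols] = cu_growth(eff, t[:, None], self.slopes[:, None])
        return out

    # -- selection -----------------------------------------------------

    def information_gain(self, posterior: Posterior, exact: bool = False) -> np.ndarray:
        """Expected posterior-entropy reduction for every candidate.

        Equals the mutual information between the (unknown) categorical
        response and the hypothesis: H(marginal response) minus the
        posterior-weighted mean response entropy.
        """
        w = posterior.mass
        if exact:
            mi = np.empty(self.n_candidates)
            for c in range(self.n_candidates):
                u = self.cu_at(float(self.cand_freqs[c]),
                               float(self.cand_levels[c]))
                p = category_probabilities(u, self.config.response_sd)
                pm = w @ p
                nz = pm > 0
                h_marg = -(pm[nz] * np.log(pm[nz])).sum()
                h_cond = w @ category_entropy(u, self.config.response_sd)
                mi[c] = h_marg - h_cond
            return mi
        active = np.flatnonzero(w > w.max() * 1e-10)
        if self.transient or active.size < 0.2 * self.n_hypotheses:
            # posterior has concentrated: histogram only the surviving mass
            W = np.bincount(
                self._flat_idx[active].ravel(),
                weights=np.repeat(w[active], self.n_candidates),
                minlength=self.n_candidates * self._K,
            ).reshape(self.n_candidates, self._K)
        else:
            W = (self._sparse_hist @ w.astype(np.float32)).reshape(
                self.n_candidates, self._K)
        pm = W @ self._bin_p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(pm > 0, pm * np.log(pm), 0.0)
        h_marg = -t.sum(axis=1)
        h_cond = W @ self._bin_h
        return h_marg - h_cond

    def select(self, posterior: Posterior, exact: bool = False) -> tuple[float, float]:
        """Greedy information-gain choice; ties break to the lowest level,
        then the lowest frequency (candidates are lexicographically ordered)."""
        mi = self.information_gain(posterior, exact=exact)
        best = int(np.flatnonzero(mi >= mi.max() - 1e-12)[0])
        return float(self.cand_freqs[best]), float(self.cand_levels[best])

    # -- likelihood / update -------------------------------------------

    def likelihoods(self, freq: float, level: float, category: int) -> np.ndarray:
        """Per-hypothesis probability of ``category`` at (freq, level),
        floored at config.likelihood_floor."""
        if not 0 <= category <= 10:
            raise InvalidConfigError("category must be in 0..10")
        u = self.cu_at(freq, level)
        p = category_probability(u, self.config.response_sd, category)
        return np.maximum(p, self.config.likelihood_floor)


def init_posterior(engine: QclsEngine) -> Posterior:
    """Uniform prior over the hypothesis grid."""
    g = engine.n_hypotheses
    if g == 0:
        raise InvalidConfigError("hypothesis grid is empty")
    return Posterior(log_mass=np.full(g, -np.log(g)), trial_count=0)


def likelihood(engine: QclsEngine, hypothesis_index: int, freq: float,
               level: float, category: int) -> float:
    """Probability of a category response under a single grid hypothesis."""
    return float(engine.likelihoods(freq, level, category)[hypothesis_index])


def update_posterior(posterior: Posterior, trial: TrialRecord,
                     engine: QclsEngine) -> Posterior:
    """Multiplicative Bayes update, renormalized in log space."""
    lik = engine.likelihoods(trial.freq, trial.level, trial.category)
    log_mass = posterior.log_mass + np.log(lik)
    norm = logsumexp(log_mass)
    if not np.isfinite(norm):
        raise FloatingPointError("posterior mass underflowed")
    return Posterior(log_mass=log_mass - norm, trial_count=posterior.trial_count + 1)


def select_next_stimulus(posterior: Posterior, engine: QclsEngine,
                         exact: bool = False) -> tuple[float, float]:
    return engine.select(posterior, exact=exact)


@dataclass
class QclsRun:
    """Result of a simulated qCLS run."""

    trials: list
    posterior: Posterior
    engine: QclsEngine = field(repr=False, default=None)
    condition: str = "tone"
    listener_id: str = ""


_ENGINE_CACHE: dict = {}
_REFINED_CACHE: dict = {}


def get_engine(config: QclsConfig = DEFAULT_CONFIG,
               bandwidth_oct: float = 0.0) -> QclsEngine:
    """Engines are expensive to build and listener-independent; cache them."""
    key = (config, float(bandwidth_oct))
    if key not in _ENGINE_CACHE:
        _ENGINE_CACHE[key] = QclsEngine(config, bandwidth_oct)
    return _ENGINE_CACHE[key]


def _refined_grids(config: QclsConfig, engine: QclsEngine,
                   mode_index: int) -> dict:
    """Fine grids centered on the posterior-mode hypothesis."""
    def t_axis(center):
        g = np.arange(center - config.refine_threshold_span,
                      center + config.refine_threshold_span + 1e-9,
                      config.refine_threshold_step)
        return tuple(np.round(np.clip(g, -25.0, 95.0), 3))

    s_center = float(engine.slopes[mode_index])
    s_grid = np.arange(s_center - config.refine_slope_span,
                       s_center + config.refine_slope_span + 1e-9,
                       config.refine_slope_step)
    return {
        "thresholds": tuple(t_axis(float(t))
                            for t in engine.thresholds[mode_index]),
        "slopes": tuple(np.round(np.clip(s_grid, 0.03, 0.25), 4)),
        "bumps": tuple(config.refine_bump_grid),
    }


def get_refined_engine(config: QclsConfig, bandwidth_oct: float,
                       grids: dict) -> QclsEngine:
    """Refined engines are shared by listeners whose coarse posterior mode
    falls in the same grid cell; the cache is bounded."""
    key = (config, float(bandwidth_oct),
           grids["thresholds"], grids["slopes"], grids["bumps"])
    if key not in _REFINED_CACHE:
        if len(_REFINED_CACHE) >= 6:
            _REFINED_CACHE.clear()
        _REFINED_CACHE[key] = QclsEngine(config, bandwidth_oct, grids=grids,
                                         transient=True)
    return _REFINED_CACHE[key]


def run_qcls(listener: ListenerModel, condition: str = "tone",
             n_trials: int | None = None, seed: int = 0,
             config: QclsConfig = DEFAULT_CONFIG,
             engine: QclsEngine | None = None,
             exact_selection: bool = False) -> QclsRun:
    """Simulate one adaptive run: select -> respond -> update, n_trials times.

    Fully reproducible from (listener, seed).  The listener's categorical
    responses are drawn with a dedicated RNG seeded by ``seed``.
    """
    stim_type, bandwidth = CONDITIONS[condition]
    if n_trials is None:
        n_trials = config.n_trials
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    if engine is None:
        engine = get_engine(config, bandwidth)
    rng = np.random.default_rng(seed)
    posterior = init_posterior(engine)
    trials = []
    for i in range(1, n_trials + 1):
        if (config.refine_after and i == config.refine_after + 1
                and n_trials > config.refine_after):
            # rebuild the grid finely around the current mode and replay
            # the evidence collected so far
            grids = _refined_grids(config, engine, posterior.mode_index())
            engine = get_refined_engine(config, bandwidth, grids)
            posterior = init_posterior(engine)
            for t in trials:
                posterior = update_posterior(posterior, t, engine)
        freq, level = engine.select(posterior, exact=exact_selection)
        spec = StimulusSpec(stim_type=stim_type, center_freq=freq,
                            bandwidth_oct=bandwidth, level=level,
                            seed=int(rng.integers(2**31)))
        category = listener.respond(spec, rng)
        trial = TrialRecord(index=i, freq=freq, level=level,
                            bandwidth_oct=bandwidth, category=category)
        posterior = update_posterior(posterior, trial, engine)
        trials.append(trial)
    return QclsRun(trials=trials, posterior=posterior, engine=engine,
                   condition=condition, listener_id=listener.listener_id)
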