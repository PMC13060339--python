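"""Synthetic listeners: ground-truth loudness surfaces and categorical
responders emulating normal-hearing (NH) and hearing-loss (HL) cohorts.

A listener is defined by

* an audiogram (dB HL at the 10 standard audiometric frequencies), which
  sets the per-frequency threshold of the categorical-loudness surface
  after conversion to dB SPL with insert-earphone reference levels;
* a loudness-growth slope (cat/dB; group means 0.10 for NH, 0.12 for HL,
  with between-listener jitter) -- the HL combination of elevated
  thresholds and steeper growth is the classic recruitment pattern;
* a bandwidth-dependent equivalent-level offset: narrow-band stimuli are
  effectively attenuated by a smooth bump peaking (for NH, quarter-octave)
  at 7 dB at 1 kHz / 60 dB SPL; one-octave noise gets 4/7 of the
  quarter-octave offset (so the quarter-vs-octave difference is 3 dB at
  the peak) and HL listeners 0.6 of the NH offset;
* a categorical response model: category = clamp(round(CU + eps), 0, 10)
  with eps ~ N(0, response_sd), response_sd default 0.8 CU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._surface import DEFAULT_BUMP, BumpShape, boundary_level, cu_growth, interp_log2
from .errors import InvalidConfigError, InvalidSpecError
from .stimuli import StimType, StimulusSpec

#: Audiometric frequencies (Hz) at which audiograms are specified.
AUDIOGRAM_FREQS = np.array(
    [250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0, 6000.0, 8000.0]
)

#: dB HL -> dB SPL conversion (insert-earphone-style reference equivalent
#: threshold sound pressure levels, dB).
RETSPL = np.array([14.0, 9.5, 6.5, 5.5, 9.5, 11.5, 13.0, 15.0, 16.0, 15.5])

_PTA_FREQS = (500.0, 1000.0, 2000.0)


@dataclass(frozen=True)
class BandwidthOffsetSurface:
    """Bandwidth-dependent equivalent-level offset G(f, L) in dB.

    ``offset = peak_db * bandwidth_factor * group_scale * bump(f, L)`` with
    a unit Gaussian bump in (log2 f, level).  Zero for tones.
    """

    peak_db: float = 7.0            # NH quarter-octave peak, dB
    octave_fraction: float = 4.0 / 7.0  # one-octave offset / quarter-octave offset
    hl_scale: float = 0.6           # HL group multiplier
    shape: BumpShape = DEFAULT_BUMP

    def bandwidth_factor(self, bandwidth_oct: float) -> float:
        if bandwidth_oct == 0:
            return 0.0
        if np.isclose(bandwidth_oct, 0.25):
            return 1.0
        if np.isclose(bandwidth_oct, 1.0):
            return self.octave_fraction
        raise InvalidSpecError(
            f"bandwidth_oct must be one of 0, 0.25, 1 (got {bandwidth_oct})"
        )

    def __call__(self, freq, level, bandwidth_oct: float, group: str = "NH"):
        factor = self.bandwidth_factor(bandwidth_oct)
        if factor == 0.0:
            return np.zeros(np.broadcast(np.asarray(freq), np.asarray(level)).shape)
        scale = self.hl_scale if group == "HL" else 1.0
        return self.peak_db * factor * scale * self.shape(freq, level)


DEFAULT_OFFSET_SURFACE = BandwidthOffsetSurface()


@dataclass(frozen=True)
class CohortParams:
    """Group-level generator parameters (the study conditions)."""

    nh_slope_mean: float = 0.10      # cat/dB
    hl_slope_mean: float = 0.12
    slope_sd: float = 0.01           # between-listener jitter
    slope_bounds: tuple = (0.07, 0.17)
    response_sd: float = 0.8         # CU
    mbld_jitter_sd: float = 0.15     # multiplicative jitter on the offset
    nh_pta_bounds: tuple = (-5.0, 15.0)
    hl_pta_bounds: tuple = (16.0, 55.0)
    offset_surface: BandwidthOffsetSurface = DEFAULT_OFFSET_SURFACE

    def __post_init__(self):
        if self.nh_pta_bounds[1] > 15.0:
            raise InvalidConfigError("NH PTA upper bound must be <= 15 dB HL")
        if not (16.0 <= self.hl_pta_bounds[0] <= self.hl_pta_bounds[1] <= 55.0):
            raise InvalidConfigError("HL PTA bounds must lie within [16, 55] dB HL")


DEFAULT_COHORT_PARAMS = CohortParams()


@dataclass
class ListenerModel:
    """Ground-truth loudness surface plus categorical response noise."""

    listener_id: str
    group: str                       # 'NH' or 'HL'
    audiogram: np.ndarray            # dB HL at AUDIOGRAM_FREQS
    slope: float                     # cat/dB (constant across frequency)
    mbld_scale: float = 1.0          # listener-specific offset multiplier
    response_sd: float = 0.8         # CU
    seed: int = 0
    offset_surface: BandwidthOffsetSurface = DEFAULT_OFFSET_SURFACE

    def __post_init__(self):
        self.audiogram = np.asarray(self.audiogram, dtype=float)
        if self.audiogram.shape != AUDIOGRAM_FREQS.shape:
            raise InvalidConfigError("audiogram must have 10 entries")

    @property
    def pta(self) -> float:
        """Pure-tone average across 0.5, 1 and 2 kHz (dB HL)."""
        idx = [int(np.where(AUDIOGRAM_FREQS == f)[0][0]) for f in _PTA_FREQS]
        return float(np.mean(self.audiogram[idx]))

    @property
    def threshold_spl(self) -> np.ndarray:
        """Per-frequency CU-surface threshold levels (dB SPL)."""
        return self.audiogram + RETSPL

    def threshold_at(self, freq):
        return interp_log2(freq, AUDIOGRAM_FREQS, self.threshold_spl)

    def bandwidth_offset(self, freq, level, bandwidth_oct: float):
        """Equivalent-level offset (dB) for this listener."""
        base = self.offset_surface(freq, level, bandwidth_oct, group=self.group)
        return self.mbld_scale * base

    def cu(self, freq, level, bandwidth_oct: float = 0.0):
        """Expected categorical units at (freq, level) for the given
        stimulus bandwidth; clamped to [0, 10] and non-decreasing in level."""
        level = np.asarray(level, dtype=float)
        eff = level - self.bandwidth_offset(freq, level, bandwidth_oct)
        return cu_growth(eff, self.threshold_at(freq), self.slope)

    def respond(self, spec: StimulusSpec, rng) -> int:
        """Single categorical response (0..10) to a stimulus."""
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        bw = 0.0 if spec.stim_type == StimType.TONE else spec.bandwidth_oct
        u = float(self.cu(spec.center_freq, spec.level, bw))
        eps = rng.normal(0.0, self.response_sd) if self.response_sd > 0 else 0.0
        return int(np.clip(np.round(u + eps), 0, 10))

    def true_boundaries(self, freqs, bandwidth_oct: float = 0.0) -> np.ndarray:
        """Noiseless category-boundary levels, shape (10, len(freqs)).

        Boundary k is the level where CU crosses k - 0.5.  With a
        level-dependent bandwidth offset this is solved by bisection.
        """
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        ks = np.arange(1, 11)
        if bandwidth_oct == 0.0:
            t = self.threshold_at(freqs)
            return boundary_level(t[None, :], self.slope, ks[:, None])
        lo = np.full((10, freqs.size), -60.0)
        hi = np.full((10, freqs.size), 180.0)
        target = (ks - 0.5)[:, None]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            val = np.vstack([self.cu(freqs, mid[i], bandwidth_oct) for i in range(10)])
            lo = np.where(val < target, mid, lo)
            hi = np.where(val < target, hi, mid)
        return 0.5 * (lo + hi)


def _sample_audiogram(rng, group: str, params: CohortParams) -> np.ndarray:
    """Flat-to-sloping audiogram constrained to the group PTA bounds."""
    logf = np.log2(AUDIOGRAM_FREQS / 1000.0)
    lo, hi = params.nh_pta_bounds if group == "NH" else params.hl_pta_bounds
    for _ in range(200):
        if group == "NH":
            base = rng.normal(5.0, 4.0)
            tilt_hi = rng.uniform(-1.0, 4.0)   # dB/oct above 1 kHz
            tilt_lo = rng.uniform(-1.0, 2.0)   # dB/oct below 500 Hz
        else:
            base = rng.uniform(15.0, 45.0)
            tilt_hi = rng.uniform(0.0, 10.0)
            tilt_lo = rng.uniform(-2.0, 2.0)
        ag = (
            base
            + tilt_hi * np.maximum(0.0, logf)
            + tilt_lo * np.maximum(0.0, -1.0 - logf)
            + rng.normal(0.0, 1.5, size=logf.size)
        )
        ag = np.clip(ag, -10.0, 110.0)
        idx = [int(np.where(AUDIOGRAM_FREQS == f)[0][0]) for f in _PTA_FREQS]
        if lo <= float(np.mean(ag[idx])) <= hi:
            return ag
    raise InvalidConfigError(f"could not sample an audiogram within PTA bounds {lo}..{hi}")


def make_listener(group: str, params: CohortParams, seed: int,
                  listener_id: str | None = None) -> ListenerModel:
    rng = np.random.default_rng(seed)
    audiogram = _sample_audiogram(rng, group, params)
    mean = params.nh_slope_mean if group == "NH" else params.hl_slope_mean
    slope = float(np.clip(rng.normal(mean, params.slope_sd), *params.slope_bounds))
    mbld_scale = float(np.clip(rng.normal(1.0, params.mbld_jitter_sd), 0.2, 1.8))
    return ListenerModel(
        listener_id=listener_id or f"{group}{seed}",
        group=group,
        audiogram=audiogram,
        slope=slope,
        mbld_scale=mbld_scale,
        response_sd=params.response_sd,
        seed=int(seed),
        offset_surface=params.offset_surface,
    )


def make_cohort(n_nh: int, n_hl: int,
                params: CohortParams | None = None,
                seed: int = 0) -> list[ListenerModel]:
    """Sample a cohort of n_nh NH + n_hl HL listeners (default 32 + 68)."""
    if n_nh < 0 or n_hl < 0:
        raise InvalidConfigError("cohort counts must be non-negative")
    params = params or DEFAULT_COHORT_PARAMS
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_nh + n_hl)]
    cohort = []
    for i in range(n_nh):
        cohort.append(make_listener("NH", params, child_seeds[i], f"NH{i:03d}"))
    for j in range(n_hl):
        cohort.append(make_listener("HL", params, child_seeds[n_nh + j], f"HL{j:03d}"))
    return cohort


def cohort_to_json(cohort: list[ListenerModel]) -> list[dict]:
    out = []
    for lst in cohort:
        out.append(
            {
                "listener_id": lst.listener_id,
                "group": lst.group,
                "audiogram": [float(v) for v in lst.audiogram],
                "slope": lst.slope,
                "mbld_scale": lst.mbld_scale,
                "response_sd": lst.response_sd,
                "seed": lst.seed,
            }
        )
    return out


def cohort_from_json(records: list[dict],
                     offset_surface: BandwidthOffsetSurface = DEFAULT_OFFSET_SURFACE
                     ) -> list[ListenerModel]:
    return [
        ListenerModel(
            listener_id=r["listener_id"],
            group=r["group"],
            audiogram=np.asarray(r["audiogram"], dtype=float),
            slope=float(r["slope"]),
            mbld_scale=float(r["mbld_scale"]),
            response_sd=float(r["response_sd"]),
            seed=int(r["seed"]),
            offset_surface=offset_surface,
        )
        for r in records
    ]
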