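"""Shared fixtures.

The expensive session fixtures (the full default cohort experiment and the
calibrated ensemble-averaging model) are shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from neacls.listeners import DEFAULT_COHORT_PARAMS, ListenerModel, make_listener
from neacls.qcls import DEFAULT_CONFIG, get_engine


@pytest.fixture(scope="session")
def tone_engine():
    return get_engine(DEFAULT_CONFIG, 0.0)


@pytest.fixture(scope="session")
def quarter_engine():
    return get_engine(DEFAULT_CONFIG, 0.25)


@pytest.fixture()
def nh_listener():
    return make_listener("NH", DEFAULT_COHORT_PARAMS, seed=42)


@pytest.fixture()
def hl_listener():
    return make_listener("HL", DEFAULT_COHORT_PARAMS, seed=43)


def grid_member_listener(engine, hyp_index: int, response_sd: float = 0.8,
                         listener_id: str = "GM") -> ListenerModel:
    """A listener whose true surface is exactly one grid hypothesis.

    The anchor frequencies are audiogram frequencies, so interpolating the
    anchor thresholds onto the audiogram grid reproduces the hypothesis
    surface exactly (for tone conditions).
    """
    from neacls._surface import ANCHOR_FREQS, interp_log2
    from neacls.listeners import AUDIOGRAM_FREQS, RETSPL

    t_anchors = engine.thresholds[hyp_index]
    slope = float(engine.slopes[hyp_index])
    t_spl = interp_log2(AUDIOGRAM_FREQS, ANCHOR_FREQS, t_anchors)
    return ListenerModel(
        listener_id=listener_id,
        group="NH",
        audiogram=np.asarray(t_spl) - RETSPL,
        slope=slope,
        mbld_scale=0.0,
        response_sd=response_sd,
        seed=0,
    )


@pytest.fixture(scope="session")
def full_experiment(tmp_path_factory):
    """Default 32 NH + 68 HL cohort, three conditions, 100 trials per run."""
    from neacls.experiment import ExperimentConfig, run_experiment

    out = tmp_path_factory.mktemp("full_experiment")
    cfg = ExperimentConfig(output_dir=str(out), seed=20)
    return run_experiment(cfg, resume=False)


@pytest.fixture(scope="session")
def calibrated_nea():
    """Reduced ensemble-averaging model (20 channels, 20 fibers/ensemble),
    calibrated to the loudness-growth and flat-noise targets."""
    from neacls.nea import EnsembleConfig, NeaModel, PeripheryParams, calibrate

    model = NeaModel(periphery=PeripheryParams(n_channels=20),
                     ensemble=EnsembleConfig(n_fibers=20))
    cal = calibrate(model, seed=3)
    return model, cal
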