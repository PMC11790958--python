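import dataclasses

import pytest

from loopx import LoopEvent, PipelineConfig, TetherSimConfig


@pytest.fixture
def noise_free_config():
    """One loop event at 1 kbp/s from t=5 s, rendered without noise."""
    return TetherSimConfig(
        n_frames=50,
        loop_events=(LoopEvent(t_start=5.0, rate=1.0, anchor_pos=0.5, max_loop=30.0),),
        noise_model="gaussian",
        gaussian_sd=0.0,
        read_noise_sd=0.0,
    )


@pytest.fixture
def pipeline_config():
    return PipelineConfig()


def noise_free(config: TetherSimConfig, **overrides) -> TetherSimConfig:
    """Copy of ``config`` with all noise sources switched off."""
    return dataclasses.replace(
        config, noise_model="gaussian", gaussian_sd=0.0, read_noise_sd=0.0, **overrides
    )
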