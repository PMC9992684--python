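import numpy as np
import pytest

from regionage.features import SelectionParams
from regionage.pipeline import PipelineConfig
from regionage.synthetic import ModalitySpec, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(seed: int = 7) -> PipelineConfig:
    """A 4+4+2-region pipeline config that runs in a couple of seconds."""
    return PipelineConfig(
        synthetic=SyntheticConfig(
            n_hc_train=60, n_hc_test=25, n_scz=25,
            atlas_spec={
                "GM": ModalitySpec(4, 40, baseline=10.0, value_scale=1.0, slope_sign=-1),
                "FC": ModalitySpec(4, 40, baseline=0.5, value_scale=0.1, slope_sign=+1),
                "FA": ModalitySpec(2, 40, baseline=0.5, value_scale=0.005, slope_sign=-1),
            },
            effect_spec={"GM": {1: 5.0, 2: 5.0}},
        ),
        selection=SelectionParams(n_inner=20, n_outer=20, count_threshold=2),
        seed=seed,
    )


@pytest.fixture
def small_pipeline_config():
    return tiny_config()
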