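import numpy as np
import pytest

from fotmech.synthetic_data import (
    DEFAULT_BASE_PARAMS,
    DEFAULT_FREQUENCIES,
    MechParams,
    build_design,
    default_effect_template,
    synthesize_waveform,
)


@pytest.fixture
def base_params() -> MechParams:
    return DEFAULT_BASE_PARAMS


@pytest.fixture
def small_design():
    """Tiny factorial design: 2 treatments x 1 dose x 1 day x 2 PEEPs, n=3."""
    return build_design(
        treatments=("HBSS", "AgNP"),
        doses=(("high", 0.5),),
        days=(7,),
        peeps=(0.0, 3.0),
        n_per_group=3,
        seed=7,
    )


@pytest.fixture
def template():
    return default_effect_template()


@pytest.fixture
def noiseless_record(base_params):
    rng = np.random.default_rng(11)
    return synthesize_waveform(
        base_params, peep=3.0, freqs=DEFAULT_FREQUENCIES, noise_sd=0.0, rng=rng
    )
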