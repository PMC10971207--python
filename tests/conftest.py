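import dataclasses

import numpy as np
import pytest

from specseg.phantom import PhantomParams, generate_phantom
from specseg.pipeline import preprocess_section
from specseg.preprocess import assemble_stack


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale phantom parameters (256 um frame) for fast unit tests."""
    return dataclasses.replace(
        PhantomParams(),
        image_height_px=256,
        image_width_px=256,
        rete_peg_amplitude_px=20.0,
        rete_peg_period_px=64.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_section(small_params):
    return generate_phantom(small_params)


@pytest.fixture(scope="session")
def small_stack(small_section):
    r1, r2, df, mask, lab = preprocess_section(small_section)
    stack, _ = assemble_stack(
        r1, r2, df, mask, labels=lab, section_id=small_section.section_id
    )
    return stack, lab


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
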