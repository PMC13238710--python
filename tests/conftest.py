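import numpy as np
import pytest

from neuroskin import RasterMask, SectionSpec, generate_section


def straight_masks(height=100, width=100, boundary=10, pixel_size=1.0):
    """Epidermis above ``boundary``, dermis below, full image width."""
    rows = np.broadcast_to(np.arange(height)[:, None], (height, width))
    epi = RasterMask(rows < boundary, pixel_size)
    dermis = RasterMask(rows >= boundary, pixel_size)
    return epi, dermis


@pytest.fixture
def straight_interface():
    return straight_masks()


@pytest.fixture(scope="session")
def default_section():
    """One seeded synthetic section at full default geometry."""
    spec = SectionSpec(seed=42)
    return generate_section(spec)


@pytest.fixture(scope="session")
def small_section():
    spec = SectionSpec(shape=(512, 512), n_crossing_fibers=6, n_dermal_fibers=3, seed=7)
    return generate_section(spec)
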