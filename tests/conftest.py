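import dataclasses

import numpy as np
import pytest

from tenomac import synth


@pytest.fixture
def small_section_spec() -> synth.SectionSpec:
    """A fast-to-render section: ~60 cells, 30% reporter-positive."""
    return synth.SectionSpec(
        width_um=300.0, height_um=180.0,
        cell_density_per_mm2=2500.0,
        macrophage_fraction=0.3,
        peritenon_band_um=20.0,
        seed=7,
    )


@pytest.fixture
def small_ish_spec() -> synth.IshSpec:
    return dataclasses.replace(
        synth.preset("ish-colocalized"),
        width_um=220.0, height_um=220.0, roi_polygon=None, seed=3)


def parallel_surfaces(width_um: float, gap_um: float):
    """Two horizontal surface polylines at y=0 and y=gap."""
    top = np.array([[0.0, 0.0], [width_um, 0.0]])
    bottom = np.array([[0.0, gap_um], [width_um, gap_um]])
    return top, bottom
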