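"""Shared fixtures: synthetic lattices and rendered volumes.

Expensive renders are session-scoped so the detection, morphometry and
acceptance tests share them.
"""

import numpy as np
import pytest

from granulattice.cells import HIAPP_BCT_CELL, HIAPP_TRICLINIC_CELL, FIVEFOLD_WEDGE_ANGLES
from granulattice.synthetic import (
    RenderSpec,
    build_twinned_assembly,
    build_unit_cell_points,
    make_cyclic_twin,
    render_volume,
)

BCT_MIN_SPACING = 0.5 * np.sqrt(2 * 27.9**2 + 33.0**2)  # shortest BCT translation


@pytest.fixture(scope="session")
def bct_cell():
    return HIAPP_BCT_CELL


@pytest.fixture(scope="session")
def triclinic_cell():
    return HIAPP_TRICLINIC_CELL


@pytest.fixture(scope="session")
def bct_points():
    """Noiseless BCT lattice, ~300 granules."""
    return build_unit_cell_points(HIAPP_BCT_CELL, box=(170.0, 170.0, 100.0))


@pytest.fixture(scope="session")
def triclinic_points():
    """Noiseless triclinic lattice, >=300 granules."""
    return build_unit_cell_points(HIAPP_TRICLINIC_CELL, box=(180.0, 180.0, 160.0))


@pytest.fixture(scope="session")
def twin_points():
    """Five-sector cyclic twin with the study wedge angles, full-size box."""
    spec = make_cyclic_twin(HIAPP_BCT_CELL, FIVEFOLD_WEDGE_ANGLES)
    return build_twinned_assembly(spec, box=(600.0, 600.0, 85.0))


@pytest.fixture(scope="session")
def bct_volume(bct_points):
    """Noiseless render of the BCT lattice at 1.1 nm voxels."""
    return render_volume(bct_points, RenderSpec())


@pytest.fixture(scope="session")
def slab_volume():
    """BCT assembly with (001) in-plane linkers for slab/class-average tests."""
    pts = build_unit_cell_points(
        HIAPP_BCT_CELL, box=(300.0, 300.0, 66.0), origin=(0.0, 0.0, 16.5)
    )
    spec = RenderSpec(linker_planes=((0.0, 0.0, 1.0),), noise_sigma=0.05, seed=11)
    return pts, render_volume(pts, spec)
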