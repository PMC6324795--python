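"""Shared fixtures: the synthetic morphology, synapse bank, calibrated cells.

Calibration (leak to the input-resistance target, somatic noise to the
0.22 mV resting sigma_Vm) runs once per session per variant; everything
downstream reuses the same calibrated cell.
"""

import numpy as np
import pytest

from is3sim import (
    CellModel,
    build_fixture_morphology,
    build_synapse_bank,
)


@pytest.fixture(scope="session")
def fixture_morph():
    return build_fixture_morphology()


@pytest.fixture(scope="session")
def bank(fixture_morph):
    return build_synapse_bank(fixture_morph)


@pytest.fixture(scope="session")
def cell_plus():
    """Fully calibrated AType+ cell (leak and noise fitted from scratch)."""
    return CellModel.calibrated("AType+")


@pytest.fixture(scope="session")
def cell_minus():
    """Fully calibrated AType- cell."""
    return CellModel.calibrated("AType-")
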