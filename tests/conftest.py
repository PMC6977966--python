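import numpy as np
import pytest

from zippercap import (
    ZipperSpec,
    build_ideal_zipper,
    extract_tips,
    thread_sequence,
)
from zippercap.scoring import native_candidate

#: Reduced sampling for tests that call the scorer many times; results are
#: deterministic at any density.
FAST_SCORE = {"n_sasa_points": 120, "sc_density": 4.0}

NACORE9 = "AVVTGVTAV"


@pytest.fixture(scope="session")
def fibril():
    """Ideal NACore-like zipper, 4 strands per sheet."""
    return build_ideal_zipper(ZipperSpec(sequence=NACORE9,
                                         n_strands_per_sheet=4))


@pytest.fixture(scope="session")
def tips(fibril):
    return extract_tips(fibril, context_layers=2)


@pytest.fixture(scope="session")
def top_tip(tips):
    return tips[0]


@pytest.fixture(scope="session")
def bottom_tip(tips):
    return tips[1]


@pytest.fixture(scope="session")
def native_pose(top_tip):
    return thread_sequence(top_tip, native_candidate(top_tip))


def backbone_coords(pose_or_atoms):
    atoms = getattr(pose_or_atoms, "atoms", pose_or_atoms)
    return np.array(
        [a.position for a in atoms if a.name in ("N", "CA", "C", "O")]
    )
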