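"""Shared fixtures: canonical solids, crowns, and the 36-tooth study run.

Everything is generated programmatically and seeded; the expensive study
fixtures are session-scoped so the technique-comparison results are
computed once and shared by the evaluation and acceptance tests.
"""

import numpy as np
import pytest

from occluwear import evaluation as ev
from occluwear import synthetic_teeth as st
from occluwear.mesh_core import SurfaceMesh

# study-scale settings used throughout the suite: crowns at 6000 faces keep
# the full 36-tooth battery within desk-scale runtimes
STUDY_RESOLUTION = 6000
STUDY_SEED = 1


def make_unit_cube() -> SurfaceMesh:
    """Unit cube [0,1]^3 with outward orientation, 8 vertices, 12 faces."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0
        [4, 6, 7], [4, 7, 5],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return SurfaceMesh(v, f)


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    return make_unit_cube()


@pytest.fixture(scope="session")
def premolar() -> SurfaceMesh:
    return st.generate_crown(st.premolar_spec(random_seed=1,
                                              mesh_resolution=3000))


@pytest.fixture(scope="session")
def molar() -> SurfaceMesh:
    return st.generate_crown(st.molar_spec(random_seed=3,
                                           mesh_resolution=3000))


@pytest.fixture(scope="session")
def worn_pair() -> st.CrownPair:
    """A premolar pair with 1 mm occlusal wear and both lateral patches."""
    return st.make_crown_pair(
        st.premolar_spec(random_seed=2, mesh_resolution=STUDY_RESOLUTION),
        st.WearSpec(occlusal_depth=1.0,
                    buccal_patch=st.PatchSpec(depth=0.2, extent=4.0),
                    lingual_patch=st.PatchSpec(side="lingual", depth=0.15,
                                               extent=3.5),
                    random_seed=4),
        displacement_seed=9)


@pytest.fixture(scope="session")
def replica36() -> list[st.StudyTooth]:
    """The full in-silico analogue of the study sample."""
    return st.study_replica(n_teeth=36, seed=STUDY_SEED,
                            mesh_resolution=STUDY_RESOLUTION)


@pytest.fixture(scope="session")
def study_config() -> ev.StudyConfig:
    return ev.StudyConfig(seed=STUDY_SEED,
                          techniques=("PC_A", "CC_B", "CC_D"))


@pytest.fixture(scope="session")
def study_rows(replica36, study_config):
    """GS + PC_A/CC_B/CC_D measurements over the 36-tooth replica."""
    return ev.run_study(replica36, study_config)


@pytest.fixture(scope="session")
def study_frame(study_rows):
    import pandas as pd  # noqa: F401 - ensures a clear error if missing
    return ev._results_frame(study_rows)
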