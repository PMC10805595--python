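import numpy as np
import pytest

from echodome.geometry import DomeSpec, TriMesh, make_dome, voxelize
from echodome.scenario import SceneCache, target_impulse_response

VARIANTS = ("T1", "T2", "T3", "T4", "T5")


@pytest.fixture(scope="session")
def dome_spec() -> DomeSpec:
    return DomeSpec()


@pytest.fixture(scope="session")
def coarse_meshes(dome_spec):
    """Dome meshes of all five variants at 1 mm meshing resolution."""
    return {v: make_dome(dome_spec.with_variant(v), mesh_resolution=1.0) for v in VARIANTS}


@pytest.fixture(scope="session")
def box_mesh() -> TriMesh:
    """Axis-aligned 10 x 10 x 10 mm closed box."""
    v = np.array(
        [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0],
         [0, 0, 10], [10, 0, 10], [10, 10, 10], [0, 10, 10]],
        dtype=float,
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
         [1, 2, 6], [1, 6, 5], [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return TriMesh(v, f)


@pytest.fixture(scope="session")
def sphere_mesh() -> TriMesh:
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return TriMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def scene_cache() -> SceneCache:
    return SceneCache()


@pytest.fixture(scope="session")
def standard_irs(dome_spec, scene_cache):
    """Baseline-subtracted impulse responses of all five targets in the
    standard 420 x 220 x 80 mm scene at dx = 1 mm (the desk-scale rerun of
    the reference echo simulation).  Computed once per session; this is the
    dominant cost of the suite."""
    return {
        v: target_impulse_response(
            dome_spec.with_variant(v), dx=1.0, cache=scene_cache, mesh_resolution=1.0
        )
        for v in VARIANTS
    }
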