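import numpy as np
import pytest
import trimesh

from atriflow import mesh_core as mc
from atriflow import synthetic_anatomy as sa


@pytest.fixture(scope="session")
def unit_cube():
    box = trimesh.creation.box(extents=(1, 1, 1))
    return mc.TriSurfaceMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


@pytest.fixture(scope="session")
def icosphere():
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return mc.TriSurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def small_sphere():
    ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)  # 320 faces
    return mc.TriSurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def straight_tube():
    spec = sa.LAACurveSpec(
        np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]]), radius=0.5)
    return sa.make_parametric_laa(spec)


@pytest.fixture(scope="session")
def semicircle_tube():
    th = np.linspace(0, np.pi, 9)
    ctrl = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
    return sa.make_parametric_laa(sa.LAACurveSpec(ctrl, radius=0.3))


@pytest.fixture(scope="session")
def template_la():
    return sa.make_template_la()


@pytest.fixture(scope="session")
def study_set2():
    return sa.make_study_set(2, seed=1)


@pytest.fixture(scope="session")
def cube_tet(unit_cube):
    return mc.tetrahedralize(unit_cube, 0.25)
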