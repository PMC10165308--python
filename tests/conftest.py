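import numpy as np
import pytest

from phantomforge import meshing, phantom as ph, pk


@pytest.fixture(scope="session")
def phantom2mm():
    """Default synthetic phantom at 2 mm spacing (shared, read-only)."""
    return ph.generate_synthetic_phantom(ph.default_synthetic_spec())


@pytest.fixture(scope="session")
def model():
    return pk.build_model()


@pytest.fixture(scope="session")
def schedule(model):
    return pk.solve_rk4(model)


@pytest.fixture(scope="session")
def liver_shell(phantom2mm):
    """Liver surface -> default smoothing -> 2 mm shell."""
    surface = meshing.extract_surface(phantom2mm,
                                      phantom2mm.label_for_role("liver"))
    smoothed = meshing.laplacian_smooth(surface)
    return meshing.extrude_shell(smoothed, 2.0)


@pytest.fixture()
def tiny_phantom():
    """Small hand-built two-label phantom for label-surgery tests."""
    labels = np.zeros((12, 12, 12), dtype=np.uint8)
    labels[2:8, 2:8, 2:8] = 1          # block organ
    labels[9, 9, 9] = 1                # detached voxel
    labels[4, 4, 4] = 2                # 1-voxel cavity of the other label
    labels[2:5, 9:11, 2:5] = 2         # second organ proper
    table = {1: ("organ A", "other"), 2: ("organ B", "other")}
    return ph.load_voxel_phantom(labels, (1.0, 1.0, 1.0), table)
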