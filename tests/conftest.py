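import numpy as np
import pytest
import trimesh

from nucmorph import (LabeledVolume, ObjectMask, PhantomSpec, TriangleMesh,
                      make_phantom, split_objects)


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def unit_icosphere() -> TriangleMesh:
    return icosphere(1.0, 3)


@pytest.fixture(scope="session")
def sphere_mask() -> ObjectMask:
    """Voxel sphere r=10 on a 36^3 grid, as a single object mask."""
    vol, _ = make_phantom(PhantomSpec("sphere", (10.0,), grid_shape=(36, 36, 36)))
    (obj,) = split_objects(vol, min_voxels=8)
    return obj


def block_volume(shape, blocks, **kwargs) -> LabeledVolume:
    """Binary volume with solid rectangular blocks given as index slices."""
    vox = np.zeros(shape, dtype=np.uint8)
    for sl in blocks:
        vox[sl] = 1
    return LabeledVolume(vox, **kwargs)
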