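import numpy as np
import pytest
from scipy import ndimage as ndi

from capnet import pipeline, synthdata


@pytest.fixture(scope="session")
def lattice_phantom():
    """Factory: (rows, cols, radius_vx, ...) -> (spec, volume, ground_truth).

    The spec returned is the centred one actually used for voxelization,
    so degradation operations can reuse its geometry.
    """

    def make(rows, cols, radius_vx=2.0, pitch_vx=14.0, orientation_deg=30.0,
             spacing_nm=150.0, removed_edges=None, seed=0):
        spec, _ = synthdata.make_lattice_network(
            rows, cols, pitch_nm=pitch_vx * spacing_nm,
            orientation_deg=orientation_deg, removed_edges=removed_edges, seed=seed,
        )
        shape = pipeline._default_phantom_shape(rows, cols, pitch_vx, radius_vx, orientation_deg)
        spec = synthdata.center_network(spec, shape, (spacing_nm,) * 3)
        vol, gt = synthdata.voxelize_network(spec, radius_vx, shape, (spacing_nm,) * 3)
        return spec, vol, gt

    return make


def cubical_euler_characteristic(mask: np.ndarray) -> int:
    """Independent oracle: Euler characteristic of the union of unit cubes.

    Counts occupied vertices, edges, faces and cubes of the cubical
    complex spanned by the foreground voxels: chi = V - E + F - C. For a
    connected set homotopy-equivalent to a graph, loops = 1 - chi.
    """
    m = np.asarray(mask, dtype=bool)
    pad = np.pad(m, 1)

    def occupied(axes):
        # a k-cell is occupied when any incident voxel is foreground;
        # incident voxels span a 2-window along every axis NOT in `axes`
        out = pad
        for ax in range(3):
            if ax not in axes:
                out = out[tuple(slice(None) if a != ax else slice(0, -1) for a in range(3))] | \
                      out[tuple(slice(None) if a != ax else slice(1, None) for a in range(3))]
        return int(out.sum())

    c = occupied((0, 1, 2))          # cubes: the voxels themselves
    f = occupied((0, 1)) + occupied((0, 2)) + occupied((1, 2))
    e = occupied((0,)) + occupied((1,)) + occupied((2,))
    v = occupied(())
    return v - e + f - c


def n_components_26(mask: np.ndarray) -> int:
    _, n = ndi.label(np.asarray(mask, bool), structure=np.ones((3, 3, 3), bool))
    return int(n)


@pytest.fixture(scope="session")
def euler_oracle():
    return cubical_euler_characteristic
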