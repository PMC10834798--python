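"""Shared helpers for the test suite."""
import numpy as np

from slamrecon.acquisition import KSpaceData


def kspace_from_voxels(voxel_fids, geometry, averages_grid=None,
                       dwell_s=1.0 / 4000.0):
    """Forward-encode an arbitrary voxel image exactly over the full grid."""
    n = geometry.matrix
    grid = np.fft.fftn(voxel_fids, axes=(0, 1, 2))
    k_index = geometry.k_indices()
    idx = k_index % np.array(n)
    samples = grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    if averages_grid is None:
        averages = np.ones(k_index.shape[0], dtype=int)
    else:
        averages = averages_grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        samples = samples * averages[:, None]
    return KSpaceData(samples=samples, k_index=k_index, averages=averages,
                      dwell_s=dwell_s, geometry=geometry)
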