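import numpy as np
import pytest

from cerebropwv.angiography import FlowVolume4D
from cerebropwv.phantom import PhantomSpec


@pytest.fixture(scope="session")
def frame_times():
    """20 frames spanning a 0.95 s cardiac cycle (t_j = (j-1)T/M)."""
    return np.arange(20) * 0.95 / 20


def make_uniform_flow(mag=1.0, vel=(0.0, 0.0, 0.0), venc=110.0, shape=(4, 4, 4), n_frames=3):
    """Tiny constant flow volume for CD formula checks."""
    t = np.linspace(0.0, 0.8, n_frames)
    full = shape + (n_frames,)
    return FlowVolume4D(
        magnitude=np.full(full, mag),
        vel_x=np.full(full, vel[0]),
        vel_y=np.full(full, vel[1]),
        vel_z=np.full(full, vel[2]),
        venc=venc,
        voxel_size=np.array([0.69, 0.69, 0.69]),
        frame_times=t,
    )


def cylinder_mask(shape=(15, 15, 48), radius=3.0, z0=4, z1=44, center=None):
    """Axis-aligned filled cylinder along z."""
    cx = center or (shape[0] // 2, shape[1] // 2)
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disk = (x - cx[0]) ** 2 + (y - cx[1]) ** 2 <= radius**2
    out = np.zeros(shape, dtype=bool)
    out[:, :, z0:z1] = disk[:, :, None]
    return out


def y_line_set():
    """Ideal Y: three diagonal arms meeting at a single junction voxel.

    Diagonal departure offsets are pairwise non-adjacent under
    26-connectivity, so the center is the only junction voxel.
    """
    center = (5, 5, 5)
    vox = [center]
    for k in range(1, 4):
        vox.append((5 + k, 5 + k, 5))  # arm A
        vox.append((5 - k, 5 + k, 5))  # arm B
        vox.append((5, 5 - k, 5))  # arm C
    arr = np.zeros((12, 12, 12), dtype=bool)
    for v in vox:
        arr[v] = True
    return arr, center


@pytest.fixture
def knot_spec():
    return PhantomSpec(true_pwv=10.0, noise_sd=0.0, seed=11)
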