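import numpy as np
import pytest

import biofet
from biofet import synthetic_data as syn


@pytest.fixture(scope="session")
def bead_tetramer():
    """Bead-model tetramer with a 154 D per-monomer dipole."""
    return biofet.gen_bead_tetramer(target_dipole=154.0, seed=11)


@pytest.fixture(scope="session")
def quiet_wobble(bead_tetramer):
    """Uniform-sigma wobble trajectory with no loop regime overrides."""
    spec = syn.WobbleSpec(
        structure=bead_tetramer, n_frames=300, seed=21, sigma=0.5, loop_regimes={}
    )
    return syn.gen_wobble_trajectory(spec)


def random_coords(rng, n=10, spread=10.0):
    return rng.uniform(-spread, spread, size=(n, 3))


def quaternion_superpose_rmsd(ref, mob):
    """Independent oracle: Horn's quaternion-eigenvector superposition RMSD."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigval = np.linalg.eigvalsh(key)[-1]
    e0 = (a**2).sum() + (b**2).sum()
    rmsd_sq = max(e0 - 2.0 * eigval, 0.0) / ref.shape[0]
    return np.sqrt(rmsd_sq)
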