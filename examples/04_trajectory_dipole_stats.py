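"""Trajectory-averaged dipole statistics with an equilibration trim.

Generates a wobble trajectory whose per-monomer dipole fluctuates around a
prescribed 154 D (ligand-free magnitude) with a 35 D spread, discards the
first 10% of frames as equilibration, and reports the pooled mean +/- SD —
the same summary one quotes for a molecular-dynamics trajectory.
"""

import numpy as np

import biofet
from biofet import synthetic_data as syn

tetramer = biofet.gen_bead_tetramer(target_dipole=154.0, seed=3)
spec = syn.WobbleSpec(structure=tetramer, n_frames=400, seed=5, sigma=0.25,
                      loop_regimes={}, dipole_fluctuation_d=35.0)
trajectory = syn.gen_wobble_trajectory(spec)

stats = biofet.trajectory_dipole_stats(trajectory, trim_fraction=0.10)
se = stats.sd / np.sqrt(len(stats.series))
print(f"trajectory dipole: {stats.mean:.1f} +/- {stats.sd:.1f} D "
      f"(SE of mean {se:.2f} D)")
for mono, value in stats.per_monomer.items():
    print(f"  monomer {mono}: {value:.1f} D")

# The pooled mean should recover the generator's 154 D truth within a couple
# of standard errors; the SD reflects the prescribed 35 D fluctuation.
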