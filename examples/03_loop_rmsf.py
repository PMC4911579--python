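"""Conformational track: loop RMSF contrast between open and closed regimes.

Wobbles a bead-model tetramer in two regimes — binding-pocket loops L3,4
(residues 35-45) and L5,6 (residues 70-75) fluctuating with per-axis sigma
2.31 A ("open", ligand-free) vs 1.155 A ("closed", ligand-bound) — and
reports the per-loop RMSF after C-alpha alignment.  Isotropic Gaussian
wobble gives RMSF = sigma*sqrt(3), so the regimes target ~4 A vs ~2 A.
"""

import biofet
from biofet import synthetic_data as syn

tetramer = biofet.gen_bead_tetramer(target_dipole=154.0, seed=1)

for regime in ("open", "closed"):
    spec = syn.WobbleSpec(structure=tetramer, n_frames=600, seed=7,
                          sigma=0.5, regime=regime)
    trajectory = syn.gen_wobble_trajectory(spec)
    profile = biofet.rmsf(trajectory, trim_fraction=0.10)
    loops = ", ".join(f"{name}: {value:.2f} A"
                      for name, value in profile.per_loop.items())
    print(f"{regime:>6s} regime -> {loops}")

# The ~2x RMSF drop from open to closed mirrors how biotin binding rigidifies
# the loops that close over the binding pocket.
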