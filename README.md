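# biofet

Toolkit for decoupling the response of organic thin-film transistor (OTFT)
biosensors into an **electrostatic** contribution — a threshold-voltage shift
set by the dipole layer of the immobilized protein — and a **conformational**
contribution — a field-effect mobility drop caused by binding-induced
disorder at the protein/semiconductor interface.  It was built around the
avidin/streptavidin–biotin system, where ligand binding both closes the
binding-pocket loops (L3,4, residues 35–45; L5,6, residues 70–75) and
roughly doubles the monomer dipole moment, but every operation is generic.

## Who it is for

Experimentalists analysing transfer curves from protein-functionalized
OTFTs, and modellers post-processing structures/trajectories of the protein
layer, who want the two analyses to meet in one quantitative comparison.

## The model

In saturation, the drain current obeys the gradual-channel expression

```
I_DS = (W / 2L) · C_i · μ_FET · (V_G − V_T)²
```

so √|I_DS| is linear in V_G on the accumulation branch: the abscissa
intercept is V_T, the slope gives μ_FET.  Differentiating at constant C_i
decouples the normalized binding response at a fixed gate bias to first
order:

```
ΔI/I₀ = Δμ/μ₀ − 2·ΔV_T / (V_G − V_T0)
```

On the structural side, the monomer dipole is the first moment of the
partial charges about the center of mass, p = Σᵢ qᵢ(rᵢ − r_COM) (reported in
debye), and a monolayer of such dipoles shifts the threshold voltage by the
Helmholtz dipole-layer potential

```
ΔV_T = M_dip / (ε₀ · ε_r · A)
```

with A the interfacial footprint of one dipole.  Loop flexibility is
quantified by per-residue RMSF after least-squares C-alpha alignment
(proper rotations only), with an equilibration trim.

## Worked example

```
python examples/02_dipole_and_helmholtz.py
```

prints

```
per-monomer dipole magnitudes (debye):
  monomer A:  283.00 D
  ...
Helmholtz dipole-layer V_T shift: 23.69 V
measured shift: 29.04 +/- 5.45 V
agreement: 0.98 SD units (within one SD: True)
```

A bead-model tetramer is built with a prescribed 283 D per-monomer dipole
(the magnitude of a biotin-loaded avidin monomer), the dipole is recomputed
from the partial charges, and the Helmholtz expression (ε_r = 3, default
footprint 1.50 nm²) converts it into a predicted threshold-voltage shift.
The prediction lands within one standard deviation of the measured
29.04 ± 5.45 V shift, supporting the electrostatic reading of the
threshold-voltage response.  The other examples cover the device track
(`01`), the open/closed loop-RMSF contrast (`03`, ≈4 Å vs ≈2 Å) and
trajectory dipole statistics (`04`).

A thin CLI mirrors the library: `biofet simulate | extract | decouple |
dipole | rmsf | bridge | report` (see `biofet --help`).

## Layout

- `src/biofet/device_model.py` — transfer-curve types, figure extraction, decoupling, replicate statistics
- `src/biofet/electrostatics.py` — charge rules, dipole moments, Helmholtz shift, Debye cutoff
- `src/biofet/trajectory_analysis.py` — superposition, RMSD/RMSF, trajectory dipole statistics
- `src/biofet/synthetic_data.py` — ground-truth generators (curves, bead tetramers, wobble trajectories)
- `src/biofet/pipeline.py`, `src/biofet/cli.py` — orchestration and the shell interface
- `docs/methods.md` — modelling assumptions, parameter choices and limitations
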