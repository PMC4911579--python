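# Methods

## Device model and figure extraction

The forward model is the gradual-channel saturation expression
I_DS = (W/2L)·C_i·μ_FET·(V_G − V_T)², signed by carrier type.  The study's
devices are p-type (negative sweeps, negative currents); extraction fits
√|I_DS| against V_G with the gate axis flipped internally so the
accumulation branch always has positive slope, and reports V_T in the
original sign convention.

**Fit-window policy.**  Manual "pick the linear segment" selection is
replaced by a reproducible rule: among contiguous windows covering at least
30% of the accumulation branch (and ≥ 4 points), the one maximizing R² of
the linear fit wins; R² is rounded at 1e−12 so numerically perfect windows
tie and the longest is taken, which makes noiseless curves invert exactly.
Points with |I| below 3× the sub-threshold floor (the median of the
smallest-|I| quartile, i.e. the leakage estimate) are excluded, and a
configurable high-|V_G| fraction can be dropped as a blunt guard against
contact-resistance roll-off — in practice the R² criterion rejects the
rolled-off region on its own.  An extraction whose best window falls below
R² = 0.90 raises an error naming the criterion rather than returning junk.

**First-order decoupling.**  Differentiating the saturation expression at
constant C_i gives ΔI/I₀ = Δμ/μ₀ − 2·ΔV_T/(V_G − V_T0), with baseline
figures μ₀, V_T0 from the pre-binding curve and the response evaluated at a
fixed gate bias (default −100 V).  Supplying two terms solves the third;
supplying all three (each measured independently from extracted figures)
leaves the closure residual, which is second-order small —
|residual| ≤ 3·δ² for perturbations of size δ.  Sign conventions were
checked for internal consistency: with (V_G − V_T0) < 0 and ΔV_T < 0 the
threshold term is positive and drives ΔI/I₀ negative, and a threshold term
of 0.16 alone predicts ΔI/I₀ = −0.32.

**Replicate statistics.**  Groups of nominally identical devices are
summarized as mean ± one SD with the relative standard deviation (RSD), and
compared with a Welch (unequal-variance) two-sided t-test at α = 0.05 —
Welch because equal variances cannot be assumed between device
architectures; a summary-statistics entry point covers published
mean/SD/n triples.  Per-device ratios are computed first and then
aggregated (rather than ratios of aggregates).

## Electrostatics

**Charges.**  The rule-based model places integer formal charges on
side-chain reference atoms at the working pH: Arg(CZ)/Lys(NZ) +1,
Asp(CG)/Glu(CD) −1; His is +1 on NE2 only below its pKa (default 6.0, so
neutral at pH 7.5); termini are optional.  This matches the qualitative
protonation picture at pH 7.5 and suffices for dipole work on neutral
monomers; full per-atom partial-charge sets (e.g. force-field or RESP
charges from a PQR-style sidecar) are the recommended input for trajectory
work and override the rules entirely.

**Dipole.**  p = Σ qᵢ(rᵢ − r_COM) about the mass-weighted center of the
selection, converted at 1 e·Å = 4.80320 D.  For neutral groups the result
is origin-independent; for net-charged groups the COM reference is a
convention and the origin-shift relation Δp = Q·Δr applies (asserted in
tests).  Monomer selections include the bound ligand when it shares the
monomer label.

**Helmholtz shift.**  ΔV_T = M_dip/(ε₀·ε_r·A) with 1 D = 3.33564×10⁻³⁰ C·m
and ε₀ = 8.8541878128×10⁻¹² F/m.  ε_r defaults to 3, typical of a dry
protein layer.  The footprint A is not a measured quantity here: the
package default of 1.50 nm² is back-derived so that the 283 D complex
dipole with ε_r = 3 yields ≈ 23.7 V, and is exposed as an explicit
configuration parameter.  Using the binding-induced dipole *change*
(283 − 154 D) instead of the complex dipole is a documented alternative the
caller can select by passing that value; the per-area surface-density
formulation was considered and not adopted as the default because it does
not reproduce the reference arithmetic.

**Debye cutoff.**  The dipole–induced-dipole energy is modelled as
U(r) = −μ²α′/(4πε₀·ε_r²·r⁶) with α′ the polarizability volume of the
semiconductor interface (a required input — no literature default is
assumed).  The cutoff radius solves |U(r_c)| = threshold, defaulting to the
thermal energy k_B·T at 297 K; a force criterion (|dU/dr| = threshold,
threshold in newtons) is available.  The closed-form sixth root is used;
tests cross-check it against a bracketing root finder.

## Trajectory analysis

**Superposition** minimizes weighted squared deviations with proper
rotations only (determinant +1; mirror fits are unphysical for proteins),
via an SVD-based solver; an independent quaternion-eigenvector oracle backs
it in the tests.  Fewer than three atoms or collinear sets raise an error.

**RMSF** trims the first 10% of frames by default (the fraction mirrors
discarding 5 ns of a 50 ns run), aligns every frame to the first kept frame
over the C-alpha selection, re-aligns once to the time-mean structure, and
reports per-atom RMSF about the mean.  Per-residue values are the C-alpha
RMSF (a heavy-atom mean is available); per-loop values average over the
loop's residue range and monomers in scope, and both individual loops and a
pooled value are reported since either convention is defensible.  The
default loops are L3,4 (35–45) and L5,6 (70–75).  Monomer averaging
defaults to all monomers of the tetramer, with a subset option.

**Trajectory dipole statistics** evaluate the per-monomer dipole per frame
after the same trim and pool (frame, monomer) magnitudes into mean ± SD,
alongside per-monomer means and the full series.

## Synthetic generators

The generators define the conditions under which the pipeline is validated.

* **Transfer curves** use the study's geometry (W = 4 mm, L = 200 μm,
  C_i = 9 nF/cm², sweep +20 → −100 V in −10 V steps, V_DS = −80 V).  Noise
  is multiplicative lognormal (device-to-device gain variation dominates in
  OTFTs) at 2% SD in the validation batches, with a constant leakage floor
  and an optional quartic soft clamp above a roll-off onset that leaves the
  sub-onset region essentially ideal while saturating the high-|V_G| tail.
  Baseline/signal pairs inject (ΔV_T, Δμ/μ₀) exactly, with independent
  noise streams derived from one seed.
* **Bead tetramers** place compact lattice clusters of C-alpha-like beads
  (uniform 1 amu masses, so COM = centroid) at tetrahedron vertices, carry a
  neutral alternating formal-charge pattern, and add a corrective ± charge
  pair that makes the per-monomer dipole match its target exactly.  Net
  monomer neutrality is enforced so the dipole target is origin-free.
* **Wobble trajectories** displace each bead by an independent isotropic
  Gaussian (per-axis σ, so RMSF = σ√3), with loop residues switching between
  σ = 2.31 Å ("open") and 1.155 Å ("closed") — the ≈ 4 Å vs ≈ 2 Å contrast
  of ligand-free vs ligand-bound binding-pocket loops.  Frames are white in
  time: adequate for fluctuation amplitudes and means, but they carry no
  autocorrelation, so passing tests say nothing about relaxation times or
  correlated motions in real dynamics.  Optional global rigid motion
  exercises the alignment; dipole scatter is imprinted by modulating the
  corrective pair along its own axis (longitudinal), which leaves the mean
  magnitude unbiased where transverse noise would inflate it (Jensen bias
  of the Euclidean norm).  Charge-carrier dummy beads are positionally
  frozen by default for the same reason.

Problem sizes used in the validation suite — 9-device batches (the
replicate count used for RSDs), 50 seeded batches for recovery medians,
300–2000 frames for fluctuation analytics — were chosen so sampling error
sits well inside the asserted tolerances.

## Bridge criterion

The Helmholtz prediction is compared with the measured threshold-voltage
shift as |prediction| − |measurement| in units of the measurement SD
(magnitudes, because measured shifts are customarily quoted as positive
magnitudes while the shift's sign is argued separately; signs are reported
alongside).  Only the measurement SD enters the criterion — the prediction
carries no propagated uncertainty because the footprint A is a convention,
not a measured quantity.

## Known limitations

* The formal-charge model ignores partial charges, pKa shifts and
  polarization; it is a stand-in for proper force-field/RESP charge sets,
  which should be supplied via charge files for quantitative dipole work.
* White-noise wobble cannot validate time-correlated observables.
* Contact-resistance roll-off is excluded robustly, not modelled
  physically; sub-threshold slope, hysteresis and bias stress are out of
  scope.
* The Debye-cutoff operation requires the caller to supply the interface
  polarizability; reported cutoff values are therefore configuration-
  dependent context, not validated outputs.
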