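"""Synthetic inputs with known ground truth.

Three generators cover both analysis tracks:

* transfer curves obeying the saturation-regime forward model, with
  multiplicative (lognormal) current noise, a constant gate-leakage floor
  and an optional soft contact-resistance roll-off at high gate bias;
* bead-model tetramers (four compact C-alpha-like clusters) carrying formal
  charges plus a corrective charge pair tuned so each monomer's dipole
  matches a prescribed magnitude exactly;
* harmonic-wobble trajectories that displace every bead by an independent
  isotropic Gaussian whose per-residue amplitude can switch between an
  "open" and a "closed" loop regime, with optional global rigid motion to
  exercise the alignment machinery, and an optional longitudinal modulation
  of the corrective charge pair that imprints a prescribed dipole
  fluctuation without biasing the mean magnitude.

Every generator is a deterministic function of its integer seed.  Frames are
independent (white) in time — adequate for fluctuation-amplitude targets,
unlike real correlated dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import EA_TO_DEBYE
from .device_model import TransferCurve
from .electrostatics import ChargedStructure
from .errors import SpecError
from .trajectory_analysis import DEFAULT_LOOPS, LoopDefinition, Trajectory

__all__ = [
    "CurveGenSpec",
    "WobbleSpec",
    "gen_transfer_curve",
    "gen_paired_transfer_curves",
    "gen_bead_tetramer",
    "gen_wobble_trajectory",
]

#: Seed offset separating the signal curve's noise stream from the baseline's.
_SIGNAL_SEED_OFFSET = 70001


# ---------------------------------------------------------------------------
# Transfer curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveGenSpec:
    """Ground truth and artifact settings for one synthetic transfer curve.

    Defaults mirror the study's devices: W = 4 mm, L = 200 μm channels on a
    300 nm SiO2 dielectric (C_i = 9 nF/cm² = 9e−5 F/m²), p-type sweeps from
    +20 V to −100 V in −10 V steps at V_DS = −80 V.
    """

    true_vt: float
    true_mu_cm2: float
    width: float = 4e-3
    length: float = 200e-6
    c_area: float = 9e-5
    v_start: float = 20.0
    v_stop: float = -100.0
    v_step: float = -10.0
    drain_bias: float = -80.0
    noise_rel: float = 0.0
    leakage: float = 0.0
    rolloff_onset: float | None = None
    polarity: str = "p"
    seed: int = 0
    device_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.v_step == 0 or (self.v_stop - self.v_start) * self.v_step <= 0:
            raise SpecError("sweep step sign inconsistent with start/stop")
        if self.noise_rel < 0:
            raise SpecError("noise_rel must be non-negative")
        if self.true_mu_cm2 <= 0:
            raise SpecError("true mobility must be positive")


def gen_transfer_curve(spec: CurveGenSpec) -> TransferCurve:
    """Forward-model a transfer curve; deterministic under a fixed seed.

    The off branch (gate bias short of threshold) carries only the leakage
    floor.  With ``rolloff_onset`` set, current magnitudes are softly clamped
    with a tanh at the level the ideal curve reaches at the onset bias,
    mimicking contact-resistance saturation at high |V_G|.
    """
    n = int(round((spec.v_stop - spec.v_start) / spec.v_step)) + 1
    vg = spec.v_start + spec.v_step * np.arange(n)
    mu_si = spec.true_mu_cm2 * 1e-4
    overdrive = vg - spec.true_vt
    on = overdrive < 0 if spec.polarity == "p" else overdrive > 0
    magnitude = 0.5 * (spec.width / spec.length) * spec.c_area * mu_si * overdrive**2
    magnitude = np.where(on, magnitude, 0.0)

    if spec.rolloff_onset is not None:
        i_max = (
            0.5 * (spec.width / spec.length) * spec.c_area * mu_si
            * (spec.rolloff_onset - spec.true_vt) ** 2
        )
        if i_max <= 0:
            raise SpecError("rolloff_onset coincides with the threshold voltage")
        # quartic soft clamp: essentially ideal below the onset current,
        # saturating towards i_max above it
        magnitude = magnitude / (1.0 + (magnitude / i_max) ** 4) ** 0.25

    rng = np.random.default_rng(spec.seed)
    if spec.noise_rel > 0:
        sigma = math.sqrt(math.log1p(spec.noise_rel**2))
        magnitude = magnitude * np.exp(rng.normal(0.0, sigma, size=n) - 0.5 * sigma**2)
    magnitude = magnitude + abs(spec.leakage)

    sign = -1.0 if spec.polarity == "p" else 1.0
    return TransferCurve(
        gate_voltage=vg,
        drain_current=sign * magnitude,
        drain_bias=spec.drain_bias,
        width=spec.width,
        length=spec.length,
        c_area=spec.c_area,
        polarity=spec.polarity,
        device_id=spec.device_id,
    )


def gen_paired_transfer_curves(
    spec: CurveGenSpec,
    delta_vt: float = 0.0,
    delta_mu_rel: float = 0.0,
) -> tuple[TransferCurve, TransferCurve]:
    """Baseline/signal pair with an injected binding perturbation.

    The signal curve is generated with ``V_T + delta_vt`` and
    ``μ·(1 + delta_mu_rel)`` and an independent noise stream derived from the
    same seed.
    """
    baseline = gen_transfer_curve(spec)
    signal_spec = replace(
        spec,
        true_vt=spec.true_vt + delta_vt,
        true_mu_cm2=spec.true_mu_cm2 * (1.0 + delta_mu_rel),
        seed=spec.seed + _SIGNAL_SEED_OFFSET,
        device_id=spec.device_id + ":signal",
    )
    return baseline, gen_transfer_curve(signal_spec)


# ---------------------------------------------------------------------------
# Bead-model tetramer
# ---------------------------------------------------------------------------

def _lattice_cluster(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Compact cubic-lattice bead cluster with mild positional jitter."""
    side = int(math.ceil(n ** (1.0 / 3.0)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:n]
    grid -= grid.mean(axis=0)
    return grid * spacing + rng.normal(0.0, 0.25, size=(n, 3))


def _pattern_charges(n: int, pattern) -> np.ndarray:
    """Resolve a charge pattern to a neutral per-residue charge array."""
    if pattern is None or (isinstance(pattern, str) and pattern == "none"):
        return np.zeros(n)
    if isinstance(pattern, str) and pattern == "alternating":
        q = np.zeros(n)
        pos = list(range(0, n, 6))
        neg = list(range(3, n, 6))
        pairs = min(len(pos), len(neg))
        q[pos[:pairs]] = 1.0
        q[neg[:pairs]] = -1.0
        return q
    q = np.asarray(list(pattern), dtype=float)
    if q.shape != (n,):
        raise SpecError("explicit charge pattern must have one value per residue")
    if abs(q.sum()) > 1e-9:
        raise SpecError(
            f"charge pattern has net charge {q.sum():+g}; monomers must be "
            "neutral for an origin-independent dipole target"
        )
    return q


def gen_bead_tetramer(
    n_monomers: int = 4,
    residues_per_monomer: int = 80,
    charge_pattern="alternating",
    target_dipole: float = 154.0,
    seed: int = 0,
    bead_spacing: float = 3.8,
    monomer_separation: float = 34.0,
) -> ChargedStructure:
    """Bead-model tetramer with an exactly prescribed per-monomer dipole.

    Each monomer is a compact cluster of C-alpha-like beads (uniform 1 amu
    masses, so the center of mass is the centroid) carrying the requested
    formal-charge pattern, kept overall neutral.  A corrective ± charge pair
    (two "DUM" dummy beads) is then placed so that the monomer dipole equals
    ``target_dipole`` debye along a seed-chosen axis, exact to floating
    precision.  The pair's indices, charge and axis are recorded in
    ``extras["dipole_pairs"]`` for the wobble generator.
    """
    if target_dipole < 0:
        raise SpecError("target dipole must be non-negative")
    rng = np.random.default_rng(seed)
    tetra = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / math.sqrt(3.0)

    names, elements, res_names, res_ids, labels = [], [], [], [], []
    positions, charges = [], []
    dipole_pairs: dict[str, dict] = {}

    for m in range(n_monomers):
        label = chr(ord("A") + m)
        direction = (
            tetra[m] if m < 4 else rng.normal(size=3) / np.linalg.norm(rng.normal(size=3))
        )
        center = direction * monomer_separation / 2.0
        beads = _lattice_cluster(residues_per_monomer, bead_spacing, rng) + center
        q = _pattern_charges(residues_per_monomer, charge_pattern)

        d0_ea = (q[:, None] * beads).sum(axis=0)  # neutral monomer: origin-free
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        needed_ea = (target_dipole / EA_TO_DEBYE) * axis - d0_ea
        span = float(np.linalg.norm(needed_ea))
        pair_q = max(1.0, span / 5.0)  # keep the pair within ~5 Å
        offset = needed_ea / (2.0 * pair_q) if span > 0 else axis * 0.5
        if span == 0:
            pair_q = 0.0
        centroid = beads.mean(axis=0)
        p_plus = centroid + offset
        p_minus = centroid - offset

        base = len(names)
        for r in range(residues_per_monomer):
            names.append("CA")
            elements.append("C")
            res_names.append("ALA")
            res_ids.append(r + 1)
            labels.append(label)
            positions.append(beads[r])
            charges.append(q[r])
        for tag, pos, qq in (("DQ1", p_plus, pair_q), ("DQ2", p_minus, -pair_q)):
            names.append(tag)
            elements.append("C")
            res_names.append("DUM")
            res_ids.append(residues_per_monomer + 1)
            labels.append(label)
            positions.append(pos)
            charges.append(qq)
        dipole_pairs[label] = {
            "plus": base + residues_per_monomer,
            "minus": base + residues_per_monomer + 1,
            "charge": pair_q,
            "axis": axis,
        }

    n = len(names)
    return ChargedStructure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_names=np.array(res_names, dtype=object),
        residue_ids=np.array(res_ids),
        monomer_labels=np.array(labels, dtype=object),
        positions=np.array(positions),
        masses=np.ones(n),
        charges=np.array(charges),
        provenance="synthetic",
        extras={"dipole_pairs": dipole_pairs, "seed": seed,
                "target_dipole_D": target_dipole},
    )


# ---------------------------------------------------------------------------
# Wobble trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WobbleSpec:
    """Settings for a harmonic (white-noise) wobble trajectory.

    ``sigma`` is the default per-axis displacement SD (Å) of every residue;
    ``per_residue_sigma`` overrides it per residue id, and residues inside a
    loop get the loop regime's amplitude instead (``loop_regimes`` maps loop
    name to (open σ, closed σ); ``regime`` selects which applies).  The
    defaults σ_open = 2.31 Å and σ_closed = 1.155 Å correspond to loop RMSF
    of σ√3 ≈ 4 Å and ≈ 2 Å, the open/closed contrast seen when biotin forces
    the binding-pocket loops shut.  Dummy charge-carrier beads ("DUM"
    residues) stay positionally frozen unless explicitly given a σ;
    ``dipole_fluctuation_d`` instead modulates the corrective charge pair
    along its own axis so the monomer dipole magnitude fluctuates with the
    given SD (debye) around its target without transverse bias.
    """

    structure: ChargedStructure
    n_frames: int = 200
    seed: int = 0
    sigma: float = 0.5
    per_residue_sigma: Mapping[int, float] | None = None
    loops: Sequence[LoopDefinition] = DEFAULT_LOOPS
    loop_regimes: Mapping[str, tuple[float, float]] | None = None
    regime: str = "open"
    rigid_motion: bool = False
    dipole_fluctuation_d: float = 0.0
    frame_spacing_ps: float = 10.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise SpecError("wobble trajectories need n_frames >= 2")
        if self.sigma < 0 or self.dipole_fluctuation_d < 0:
            raise SpecError("sigma values must be non-negative")
        if self.regime not in ("open", "closed"):
            raise SpecError("regime must be 'open' or 'closed'")


#: Per-axis sigmas realizing the open/closed loop contrast (RMSF = σ√3).
DEFAULT_LOOP_REGIMES = {"L3,4": (2.31, 1.155), "L5,6": (2.31, 1.155)}


def _per_atom_sigma(spec: WobbleSpec) -> np.ndarray:
    top = spec.structure
    sig = np.full(top.n_atoms, spec.sigma)
    is_dummy = np.array([str(r) == "DUM" for r in top.residue_names])
    sig[is_dummy] = 0.0
    if spec.per_residue_sigma:
        for rid, s in spec.per_residue_sigma.items():
            sig[top.residue_ids == rid] = s
    regimes = spec.loop_regimes if spec.loop_regimes is not None else DEFAULT_LOOP_REGIMES
    pick = 0 if spec.regime == "open" else 1
    for loop in spec.loops:
        if loop.name not in regimes:
            continue
        mask = (top.residue_ids >= loop.first_residue) & (
            top.residue_ids <= loop.last_residue
        ) & ~is_dummy
        if loop.monomers is not None:
            allowed = set(loop.monomers)
            mask &= np.array([str(m) in allowed for m in top.monomer_labels])
        sig[mask] = regimes[loop.name][pick]
    if np.any(sig < 0):
        raise SpecError("negative sigma encountered")
    return sig


def gen_wobble_trajectory(spec: WobbleSpec) -> Trajectory:
    """Independent-frame Gaussian wobble around the base structure.

    Draw order (fixed for determinism): positional noise, then dipole-pair
    modulation, then rigid motion.  A fixed seed gives a bit-identical
    trajectory.
    """
    top = spec.structure
    rng = np.random.default_rng(spec.seed)
    sig = _per_atom_sigma(spec)
    noise = rng.normal(size=(spec.n_frames, top.n_atoms, 3)) * sig[None, :, None]
    frames = top.positions[None, :, :] + noise

    if spec.dipole_fluctuation_d > 0:
        pairs = top.extras.get("dipole_pairs", {})
        if not pairs:
            raise SpecError(
                "dipole_fluctuation_d requires a structure with recorded "
                "dipole pairs (see gen_bead_tetramer)"
            )
        for info in pairs.values():
            if info["charge"] == 0:
                continue
            delta_d = rng.normal(0.0, spec.dipole_fluctuation_d, size=spec.n_frames)
            shift = (delta_d / EA_TO_DEBYE / (2.0 * info["charge"]))[:, None] * info["axis"]
            frames[:, info["plus"], :] += shift
            frames[:, info["minus"], :] -= shift

    if spec.rigid_motion:
        rots = Rotation.random(spec.n_frames, rng=rng)
        trans = rng.normal(0.0, 5.0, size=(spec.n_frames, 3))
        for j in range(spec.n_frames):
            frames[j] = frames[j] @ rots[j].as_matrix().T + trans[j]

    return Trajectory(topology=top, frames=frames,
                      frame_spacing_ps=spec.frame_spacing_ps)
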