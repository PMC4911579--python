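"""Protein-layer electrostatics: dipoles, Helmholtz shift, Debye cutoff.

The electric dipole moment of a monomer (plus bound ligand, when present) is
the first moment of its partial-charge distribution about the monomer's
center of mass,

    p = Σ_i q_i (r_i − r_COM),

reported in debye (1 e·Å = 4.80320 D).  A monolayer of such dipoles standing
on the gate dielectric shifts the transistor threshold voltage by the
Helmholtz dipole-layer potential ΔV_T = M_dip/(ε₀ ε_r A), with A the
footprint of the outermost protein portion facing the channel.  Whether a
protein dipole can polarize the semiconductor at all is bounded by the Debye
(dipole–induced-dipole) interaction, whose r⁻⁶ energy defines a cutoff
radius once compared against a thermal threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import (
    DEBYE_TO_CM,
    DEFAULT_FOOTPRINT_NM2,
    DEFAULT_PROTEIN_EPS_R,
    EA_TO_DEBYE,
    EPS0,
    KB,
    ROOM_TEMPERATURE_K,
)
from .errors import InvalidParameterError, SelectionError

__all__ = [
    "ChargedStructure",
    "DipoleResult",
    "assign_residue_charges",
    "dipole_moment",
    "helmholtz_vt_shift",
    "debye_cutoff",
]

logger = logging.getLogger(__name__)

# Formal-charge rules for ionizable side chains near neutral pH: the
# guanidinium/ammonium groups of Arg/Lys stay protonated (+1), the
# carboxylates of Asp/Glu deprotonated (−1).  His is titrable with a default
# pKa of 6.0 and is +1 only below it.  The charge is placed on a single
# side-chain reference atom.
_SIDECHAIN_CHARGES = {"ARG": ("CZ", +1.0), "LYS": ("NZ", +1.0),
                      "ASP": ("CG", -1.0), "GLU": ("CD", -1.0)}
_HIS_REF_ATOM = "NE2"
_NEUTRAL_RESIDUES = {
    "ALA", "ASN", "CYS", "GLN", "GLY", "ILE", "LEU", "MET", "PHE", "PRO",
    "SER", "THR", "TRP", "TYR", "VAL", "DUM",
}


@dataclass(frozen=True)
class ChargedStructure:
    """Atoms with positions, masses, partial charges and group labels.

    ``monomer_labels`` identify the tetramer subunits (typically PDB chain
    identifiers).  ``provenance`` records where the charges came from
    (``"rule-based-pH<x>"``, ``"charge-file"``, ``"synthetic"``) and is
    ``None`` while the structure is uncharged.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_ids: np.ndarray
    monomer_labels: np.ndarray
    positions: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    provenance: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("atom_names", "elements", "residue_names", "monomer_labels"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=object))
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, dtype=int))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "charges", np.asarray(self.charges, dtype=float))
        if self.positions.shape != (n, 3):
            raise InvalidParameterError("positions must have shape (n_atoms, 3)")
        for name in ("elements", "residue_names", "residue_ids", "monomer_labels",
                     "masses", "charges"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"{name} length does not match atom count")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        if np.any(self.masses <= 0):
            raise InvalidParameterError("masses must be positive")
        if any(not str(m) for m in self.monomer_labels):
            raise InvalidParameterError("monomer labels must be non-empty")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def monomers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.monomer_labels:
            seen.setdefault(str(m), None)
        return tuple(seen)

    def select(
        self,
        monomers: Sequence[str] | None = None,
        residue_range: tuple[int, int] | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria (``None`` = no filter)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if monomers is not None:
            allowed = {str(m) for m in monomers}
            mask &= np.array([str(m) in allowed for m in self.monomer_labels])
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self.residue_ids >= lo) & (self.residue_ids <= hi)
        if atom_names is not None:
            allowed = set(atom_names)
            mask &= np.array([str(a) in allowed for a in self.atom_names])
        return np.flatnonzero(mask)

    def total_charge(self, indices: np.ndarray | None = None) -> float:
        q = self.charges if indices is None else self.charges[indices]
        return float(q.sum())

    def center_of_mass(self, indices: np.ndarray | None = None,
                       coords: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if coords is None else coords
        if indices is not None:
            pos, m = pos[indices], self.masses[indices]
        else:
            m = self.masses
        return (pos * m[:, None]).sum(axis=0) / m.sum()


@dataclass(frozen=True)
class DipoleResult:
    """Dipole vector (debye) of one atom group, about its center of mass."""

    magnitude: float
    vector: np.ndarray
    group: str
    frame_index: int | str = "static"


def assign_residue_charges(
    structure: ChargedStructure,
    ph: float = 7.5,
    his_pka: float = 6.0,
    include_termini: bool = False,
) -> ChargedStructure:
    """Place formal charges on ionizable residues at the given pH.

    Arg/Lys get +1 (on CZ/NZ), Asp/Glu get −1 (on CG/CD); His gets +1 on NE2
    only when ``ph < his_pka``.  With ``include_termini`` the first atom of
    each monomer's first residue gets +1 and the last residue's C/OXT gets
    −1.  Unknown residue names trigger a warning and stay neutral.
    """
    if not 0.0 <= ph <= 14.0:
        raise InvalidParameterError("pH must lie in [0, 14]")
    charges = np.zeros(structure.n_atoms)
    warned: set[str] = set()

    res_key = list(zip(structure.monomer_labels, structure.residue_ids))
    # iterate residues in order of first appearance
    first_idx: dict[tuple, list[int]] = {}
    for i, key in enumerate(res_key):
        first_idx.setdefault(key, []).append(i)

    for key, idx in first_idx.items():
        res_name = str(structure.residue_names[idx[0]]).upper()
        charge_spec = None
        if res_name in _SIDECHAIN_CHARGES:
            charge_spec = _SIDECHAIN_CHARGES[res_name]
        elif res_name == "HIS":
            if ph < his_pka:
                charge_spec = (_HIS_REF_ATOM, +1.0)
        elif res_name not in _NEUTRAL_RESIDUES:
            if res_name not in warned:
                warned.add(res_name)
                warnings.warn(
                    f"unknown residue name {res_name!r}: assigned zero charge",
                    stacklevel=2,
                )
        if charge_spec is None:
            continue
        ref_atom, q = charge_spec
        names = [str(structure.atom_names[i]) for i in idx]
        target = idx[names.index(ref_atom)] if ref_atom in names else idx[0]
        if ref_atom not in names:
            logger.info("residue %s %s lacks %s; charge placed on first atom",
                        res_name, key, ref_atom)
        charges[target] += q

    if include_termini:
        for mono in structure.monomers:
            midx = structure.select(monomers=[mono])
            rids = structure.residue_ids[midx]
            first_res = midx[rids == rids.min()]
            last_res = midx[rids == rids.max()]
            names_f = [str(structure.atom_names[i]) for i in first_res]
            names_l = [str(structure.atom_names[i]) for i in last_res]
            n_at = first_res[names_f.index("N")] if "N" in names_f else first_res[0]
            if "OXT" in names_l:
                c_at = last_res[names_l.index("OXT")]
            elif "C" in names_l:
                c_at = last_res[names_l.index("C")]
            else:
                c_at = last_res[-1]
            charges[n_at] += 1.0
            charges[c_at] -= 1.0

    return replace(structure, charges=charges, provenance=f"rule-based-pH{ph:g}")


def dipole_moment(
    structure: ChargedStructure,
    group: str | None = None,
    indices: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    frame_index: int | str = "static",
) -> DipoleResult:
    """Dipole moment of a monomer (or arbitrary selection), in debye.

    The origin is the mass-weighted center of the selection, so for
    overall-neutral groups the result is origin-independent.  ``coords``
    substitutes trajectory-frame positions for the topology positions.

    Raises :class:`SelectionError` when the selection is empty.
    """
    if indices is None:
        indices = structure.select(monomers=[group] if group is not None else None)
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise SelectionError(f"selection {group!r} matched no atoms")
    pos = (structure.positions if coords is None else np.asarray(coords, float))[indices]
    com = structure.center_of_mass(indices=indices, coords=coords)
    vec_ea = (structure.charges[indices, None] * (pos - com)).sum(axis=0)
    vector = vec_ea * EA_TO_DEBYE
    return DipoleResult(
        magnitude=float(np.linalg.norm(vector)),
        vector=vector,
        group=group if group is not None else "all",
        frame_index=frame_index,
    )


def helmholtz_vt_shift(
    dipole_debye: float,
    eps_r: float = DEFAULT_PROTEIN_EPS_R,
    area_nm2: float = DEFAULT_FOOTPRINT_NM2,
) -> float:
    """Threshold-voltage shift of a dipole monolayer: M/(ε₀ ε_r A), volts.

    ``dipole_debye`` is the per-protein dipole magnitude in debye, ``area_nm2``
    the interfacial footprint of one dipole in nm².  Linear in the dipole,
    inversely proportional to permittivity and footprint.
    """
    if area_nm2 <= 0:
        raise InvalidParameterError("footprint area must be positive")
    if eps_r < 1:
        raise InvalidParameterError("relative permittivity must be >= 1")
    m_si = dipole_debye * DEBYE_TO_CM
    return m_si / (EPS0 * eps_r * area_nm2 * 1e-18)


def debye_cutoff(
    dipole_debye: float,
    polarizability_volume_a3: float,
    eps_r: float = 1.0,
    threshold: float | None = None,
    temperature_k: float = ROOM_TEMPERATURE_K,
    criterion: str = "energy",
) -> float:
    """Cutoff radius (nm) of the dipole–induced-dipole (Debye) interaction.

    The interaction energy with a medium of polarizability volume α′ (Å³) is
    ``U(r) = −μ² α′ / (4πε₀ ε_r² r⁶)``; the cutoff is where |U| (default
    criterion, threshold defaulting to k_B·T at ``temperature_k``) or the
    magnitude of its radial derivative (``criterion="force"``, threshold in
    newtons, required) drops to the threshold.  Scales as
    ``(μ²α′/threshold)^{1/6}`` for the energy criterion.
    """
    if min(dipole_debye, polarizability_volume_a3, eps_r) <= 0:
        raise InvalidParameterError("dipole, polarizability and eps_r must be positive")
    mu = dipole_debye * DEBYE_TO_CM
    alpha = polarizability_volume_a3 * 1e-30  # m^3
    coeff = mu**2 * alpha / (4.0 * math.pi * EPS0 * eps_r**2)  # J·m^6
    if criterion == "energy":
        thr = KB * temperature_k if threshold is None else threshold
        if thr <= 0:
            raise InvalidParameterError("energy threshold must be positive (got 0: |U| never reaches it)")
        r_m = (coeff / thr) ** (1.0 / 6.0)
    elif criterion == "force":
        if threshold is None or threshold <= 0:
            raise InvalidParameterError("force criterion requires a positive threshold in newtons")
        r_m = (6.0 * coeff / threshold) ** (1.0 / 7.0)
    else:
        raise InvalidParameterError("criterion must be 'energy' or 'force'")
    return r_m * 1e9
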