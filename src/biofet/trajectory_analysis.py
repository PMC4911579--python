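"""Rigid-body superposition and fluctuation analysis of trajectories.

Implements least-squares superposition (proper rotations only), per-frame
RMSD series, per-residue/per-loop RMSF after alignment, and trajectory
statistics of the per-monomer dipole moment.  The loop summaries default to
the two surface loops that close over bound biotin in avidin-family
tetramers: L3,4 (residues 35–45) and L5,6 (residues 70–75).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .electrostatics import ChargedStructure, dipole_moment
from .errors import (
    ConfigurationError,
    EmptyAnalysisError,
    InvalidParameterError,
    SelectionError,
    SuperpositionError,
)

__all__ = [
    "Trajectory",
    "LoopDefinition",
    "RmsfProfile",
    "DipoleStats",
    "DEFAULT_LOOPS",
    "superpose",
    "rmsd_series",
    "rmsf",
    "trajectory_dipole_stats",
]


@dataclass(frozen=True)
class Trajectory:
    """An ordered frame series over one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å.  ``frame_spacing_ps``
    is the time between saved frames (default 10 ps).
    """

    topology: ChargedStructure
    frames: np.ndarray
    frame_spacing_ps: float = 10.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", fr)
        if fr.ndim != 3 or fr.shape[2] != 3:
            raise InvalidParameterError("frames must have shape (n_frames, n_atoms, 3)")
        if fr.shape[1] != self.topology.n_atoms:
            raise InvalidParameterError(
                f"frames have {fr.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if fr.shape[0] < 1:
            raise InvalidParameterError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class LoopDefinition:
    """A named residue range, optionally restricted to some monomers."""

    name: str
    first_residue: int
    last_residue: int
    monomers: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise InvalidParameterError("loop residue range must have first <= last")


#: Binding-pocket loops of the avidin-family beta barrel.
DEFAULT_LOOPS = (
    LoopDefinition("L3,4", 35, 45),
    LoopDefinition("L5,6", 70, 75),
)


@dataclass(frozen=True)
class RmsfProfile:
    """Per-atom/per-residue/per-loop fluctuation amplitudes (Å)."""

    per_atom: np.ndarray
    per_residue: pd.DataFrame  # columns: monomer, residue_id, rmsf_A
    per_loop: dict
    alignment_selection: str
    n_frames_used: int


@dataclass(frozen=True)
class DipoleStats:
    """Trajectory statistics of per-monomer dipole magnitudes (debye)."""

    mean: float
    sd: float
    series: pd.DataFrame  # columns: frame, monomer, magnitude_D
    per_monomer: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t mapping mobile onto reference.

    Minimizes the (weighted) squared deviation; reflections are rejected, so
    the rotation determinant is +1.  Returns ``(R, t, rmsd)`` with the
    post-fit RMSD in the units of the inputs; apply as ``x @ R.T + t``.

    Raises :class:`SuperpositionError` for fewer than 3 atoms or collinear
    (rank-deficient) coordinate sets.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise SuperpositionError(
            "superposition requires two equally shaped (n>=3, 3) coordinate sets"
        )
    w = np.ones(ref.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (ref.shape[0],) or np.any(w < 0) or w.sum() <= 0:
        raise SuperpositionError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    ref_c = (ref * wn[:, None]).sum(axis=0)
    mob_c = (mob * wn[:, None]).sum(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    cov = (b * wn[:, None]).T @ a
    scale = max(np.abs(cov).max(), 1e-300)
    if np.linalg.matrix_rank(cov, tol=1e-9 * scale) < 2:
        raise SuperpositionError(
            "coordinates are collinear/degenerate; rotation is underdetermined"
        )
    rot, _ = Rotation.align_vectors(a, b, weights=w)
    r_mat = rot.as_matrix()
    t = ref_c - r_mat @ mob_c
    fitted = b @ r_mat.T
    rmsd = float(np.sqrt((wn[:, None] * (a - fitted) ** 2).sum()))
    return r_mat, t, rmsd


def _resolve_indices(topology: ChargedStructure, selection) -> np.ndarray:
    """Selection -> atom indices.  None = C-alphas if present, else all atoms."""
    if selection is None:
        ca = topology.select(atom_names=["CA"])
        return ca if ca.size else np.arange(topology.n_atoms)
    if isinstance(selection, str):
        idx = topology.select(atom_names=[selection])
        if idx.size == 0:
            raise SelectionError(f"atom name {selection!r} matched no atoms")
        return idx
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty selection")
    return idx


def _trim_count(n_frames: int, trim_frames: int | None, trim_fraction: float) -> int:
    k = trim_frames if trim_frames is not None else int(round(trim_fraction * n_frames))
    if k < 0:
        raise InvalidParameterError("equilibration trim must be non-negative")
    return k


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(
    trajectory: Trajectory,
    reference: int | np.ndarray = 0,
    align_selection=None,
    analysis_selection=None,
) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference after rigid superposition.

    Each frame is superposed on the reference over ``align_selection``
    (default: all C-alpha atoms) and the RMSD is evaluated over
    ``analysis_selection`` (default: same as alignment).
    """
    top = trajectory.topology
    ai = _resolve_indices(top, align_selection)
    an = ai if analysis_selection is None else _resolve_indices(top, analysis_selection)
    ref = (
        trajectory.frames[reference]
        if isinstance(reference, (int, np.integer))
        else np.asarray(reference, dtype=float)
    )
    out = np.empty(trajectory.n_frames)
    for j, frame in enumerate(trajectory.frames):
        r_mat, t, _ = superpose(ref[ai], frame[ai])
        moved = frame[an] @ r_mat.T + t
        out[j] = np.sqrt(((ref[an] - moved) ** 2).sum(axis=1).mean())
    return out


def rmsf(
    trajectory: Trajectory,
    align_selection=None,
    trim_frames: int | None = None,
    trim_fraction: float = 0.10,
    loops: Sequence[LoopDefinition] = DEFAULT_LOOPS,
    per_residue_mode: str = "calpha",
) -> RmsfProfile:
    """Per-residue and per-loop RMSF (Å) after equilibration trim and alignment.

    The first ``trim_frames`` frames (default: ``trim_fraction`` of the
    trajectory, mirroring discarding 5 ns of a 50 ns run) are removed.  Every
    remaining frame is aligned to the first kept frame over
    ``align_selection`` (default C-alphas), the time-mean structure is
    formed, and frames are re-aligned once to that mean before computing

        RMSF_i = sqrt( <|x_i(t) − <x_i>|²>_t ).

    Per-residue values are the C-alpha RMSF (``per_residue_mode="calpha"``)
    or the mean over the residue's atoms (``"mean"``).  Per-loop values
    average the per-residue values over the loop's residue range and monomer
    scope; a ``"pooled"`` entry averages over all loops together.
    """
    k = _trim_count(trajectory.n_frames, trim_frames, trim_fraction)
    frames = trajectory.frames[k:]
    if frames.shape[0] < 2:
        raise EmptyAnalysisError(
            f"{frames.shape[0]} frame(s) left after trimming {k}; need >= 2"
        )
    top = trajectory.topology
    ai = _resolve_indices(top, align_selection)

    aligned = np.empty_like(frames)
    ref = frames[0]
    for j, frame in enumerate(frames):
        r_mat, t, _ = superpose(ref[ai], frame[ai])
        aligned[j] = frame @ r_mat.T + t
    mean_structure = aligned.mean(axis=0)
    for j, frame in enumerate(frames):
        r_mat, t, _ = superpose(mean_structure[ai], frame[ai])
        aligned[j] = frame @ r_mat.T + t
    mean_structure = aligned.mean(axis=0)
    per_atom = np.sqrt(((aligned - mean_structure) ** 2).sum(axis=2).mean(axis=0))

    records = []
    seen: dict[tuple, dict] = {}
    for i in range(top.n_atoms):
        key = (str(top.monomer_labels[i]), int(top.residue_ids[i]))
        rec = seen.setdefault(key, {"values": [], "ca": None})
        rec["values"].append(per_atom[i])
        if str(top.atom_names[i]) == "CA":
            rec["ca"] = per_atom[i]
    for (mono, rid), rec in seen.items():
        if per_residue_mode == "calpha" and rec["ca"] is not None:
            value = rec["ca"]
        else:
            value = float(np.mean(rec["values"]))
        records.append({"monomer": mono, "residue_id": rid, "rmsf_A": float(value)})
    per_residue = pd.DataFrame.from_records(records)

    per_loop: dict[str, float] = {}
    pooled: list[float] = []
    for loop in loops:
        sel = per_residue[
            (per_residue.residue_id >= loop.first_residue)
            & (per_residue.residue_id <= loop.last_residue)
        ]
        if loop.monomers is not None:
            sel = sel[sel.monomer.isin(loop.monomers)]
        if len(sel):
            per_loop[loop.name] = float(sel.rmsf_A.mean())
            pooled.extend(sel.rmsf_A.tolist())
    if pooled:
        per_loop["pooled"] = float(np.mean(pooled))

    sel_label = "CA" if align_selection is None else str(align_selection)
    return RmsfProfile(
        per_atom=per_atom,
        per_residue=per_residue,
        per_loop=per_loop,
        alignment_selection=sel_label,
        n_frames_used=int(frames.shape[0]),
    )


# ---------------------------------------------------------------------------
# Trajectory dipole statistics
# ---------------------------------------------------------------------------

def trajectory_dipole_stats(
    trajectory: Trajectory,
    monomers: Sequence[str] | None = None,
    trim_frames: int | None = None,
    trim_fraction: float = 0.10,
) -> DipoleStats:
    """Time statistics of the per-monomer dipole magnitude, pooled over monomers.

    Charges must already be present on the topology (rule-based assignment,
    a charge file, or a synthetic generator); raises
    :class:`ConfigurationError` otherwise.  The mean and SD pool all
    (frame, monomer) magnitudes after the equilibration trim; per-monomer
    means are also reported.
    """
    top = trajectory.topology
    if top.provenance is None:
        raise ConfigurationError(
            "topology has no charge provenance; assign charges before "
            "computing dipole statistics"
        )
    k = _trim_count(trajectory.n_frames, trim_frames, trim_fraction)
    frames = trajectory.frames[k:]
    if frames.shape[0] < 1:
        raise EmptyAnalysisError("no frames left after equilibration trim")
    groups = tuple(monomers) if monomers is not None else top.monomers
    idx_by_group = {g: top.select(monomers=[g]) for g in groups}

    rows = []
    for j, frame in enumerate(frames):
        for g in groups:
            res = dipole_moment(top, group=g, indices=idx_by_group[g],
                                coords=frame, frame_index=k + j)
            rows.append({"frame": k + j, "monomer": g, "magnitude_D": res.magnitude})
    series = pd.DataFrame.from_records(rows)
    values = series.magnitude_D.to_numpy()
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    per_monomer = {
        g: float(series[series.monomer == g].magnitude_D.mean()) for g in groups
    }
    return DipoleStats(mean=mean, sd=sd, series=series, per_monomer=per_monomer)
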