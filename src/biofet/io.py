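"""Readers and writers for the package's external formats.

Current–voltage sweeps travel as delimited text with a ``v_g``/``i_ds``
header and a YAML sidecar for device metadata; structures and trajectories
travel as PDB (multi-model for frame series) or plain XYZ, read and written
through MDAnalysis.  Partial charges, which PDB cannot carry, use a
whitespace-delimited ``serial charge`` sidecar (a PQR charge column is also
accepted).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .device_model import TransferCurve
from .electrostatics import ChargedStructure
from .errors import ConfigurationError, DataConventionError
from .trajectory_analysis import Trajectory

__all__ = [
    "read_transfer_curve",
    "write_transfer_curve",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_charge_file",
    "write_charge_file",
    "write_json",
]


# ---------------------------------------------------------------------------
# Current–voltage sweeps
# ---------------------------------------------------------------------------

def write_transfer_curve(curve: TransferCurve, data_path, meta_path=None, sep="\t") -> None:
    """Write the sweep as delimited text plus a YAML metadata sidecar."""
    df = pd.DataFrame({
        "v_g": curve.gate_voltage,
        "i_ds": curve.drain_current,
        "v_ds": np.full(curve.gate_voltage.size, curve.drain_bias),
    })
    df.to_csv(data_path, sep=sep, index=False)
    if meta_path is not None:
        meta = {
            "device_id": curve.device_id,
            "width_m": curve.width,
            "length_m": curve.length,
            "c_area_f_per_m2": curve.c_area,
            "polarity": curve.polarity,
            "drain_bias_v": curve.drain_bias,
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_transfer_curve(data_path, meta_path=None, **metadata) -> TransferCurve:
    """Read a sweep from delimited text.

    Device metadata comes from the YAML sidecar or keyword overrides
    (``width``, ``length``, ``c_area``, ``polarity``, ``device_id``,
    ``drain_bias``); keywords win.
    """
    df = pd.read_csv(data_path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "v_g" not in cols or "i_ds" not in cols:
        raise DataConventionError(
            f"{data_path}: required columns v_g and i_ds not found "
            f"(got {list(df.columns)})"
        )
    meta: dict = {}
    if meta_path is not None:
        raw = yaml.safe_load(Path(meta_path).read_text()) or {}
        meta = {
            "width": raw.get("width_m"),
            "length": raw.get("length_m"),
            "c_area": raw.get("c_area_f_per_m2"),
            "polarity": raw.get("polarity", "p"),
            "device_id": raw.get("device_id", ""),
            "drain_bias": raw.get("drain_bias_v"),
        }
    meta.update(metadata)
    for key in ("width", "length", "c_area"):
        if meta.get(key) is None:
            raise ConfigurationError(
                f"{data_path}: device metadata {key!r} missing (sidecar or keyword)"
            )
    drain_bias = meta.get("drain_bias")
    if drain_bias is None:
        drain_bias = float(df[cols["v_ds"]].iloc[0]) if "v_ds" in cols else 0.0
    return TransferCurve(
        gate_voltage=df[cols["v_g"]].to_numpy(float),
        drain_current=df[cols["i_ds"]].to_numpy(float),
        drain_bias=float(drain_bias),
        width=float(meta["width"]),
        length=float(meta["length"]),
        c_area=float(meta["c_area"]),
        polarity=meta.get("polarity", "p"),
        device_id=str(meta.get("device_id", "")),
    )


# ---------------------------------------------------------------------------
# Structures and trajectories (PDB / XYZ via MDAnalysis)
# ---------------------------------------------------------------------------

def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader
    return mda, MemoryReader


def _universe_from_structure(structure: ChargedStructure, frames: np.ndarray):
    mda, MemoryReader = _import_mda()
    n = structure.n_atoms
    res_keys: list[tuple] = []
    atom_resindex = np.empty(n, dtype=int)
    for i in range(n):
        key = (str(structure.monomer_labels[i]), int(structure.residue_ids[i]))
        if not res_keys or res_keys[-1] != key:
            if key in res_keys:
                raise DataConventionError("residues must be contiguous per monomer")
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    seg_labels: list[str] = []
    residue_segindex = np.empty(len(res_keys), dtype=int)
    res_names, res_ids = [], []
    for r, (mono, rid) in enumerate(res_keys):
        if mono not in seg_labels:
            seg_labels.append(mono)
        residue_segindex[r] = seg_labels.index(mono)
        res_ids.append(rid)
    res_names = [None] * len(res_keys)
    for i in range(n):
        res_names[atom_resindex[i]] = str(structure.residue_names[i])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=len(res_keys), n_segments=len(seg_labels),
            atom_resindex=atom_resindex, residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in structure.atom_names])
        u.add_TopologyAttr("elements", [str(x) for x in structure.elements])
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", res_ids)
        u.add_TopologyAttr("segids", seg_labels)
        u.add_TopologyAttr("chainIDs", [str(m) for m in structure.monomer_labels])
        u.add_TopologyAttr("masses", structure.masses)
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.load_new(np.asarray(frames, dtype=np.float32), format=MemoryReader)
    return u


def write_structure(structure: ChargedStructure, path) -> None:
    """Write a structure to PDB (single model) or XYZ."""
    write_trajectory(structure, structure.positions[None, :, :], path)


def write_trajectory(structure: ChargedStructure, frames, path) -> None:
    """Write a frame series as multi-model PDB or XYZ, by file extension."""
    mda, _ = _import_mda()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    u = _universe_from_structure(structure, frames)
    multiframe = frames.shape[0] > 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=structure.n_atoms,
                        multiframe=multiframe) as writer:
            for _ in u.trajectory:
                writer.write(u.atoms)


def _structure_from_universe(u, charges=None, provenance=None) -> ChargedStructure:
    atoms = u.atoms
    # altloc policy: keep the first alternate location, drop the rest
    if hasattr(atoms, "altLocs"):
        keep = np.array([al in ("", " ", "A") for al in atoms.altLocs])
        atoms = atoms[keep]
    n = len(atoms)
    names = atoms.names if hasattr(atoms, "names") else np.array(["X"] * n)
    if hasattr(atoms, "elements"):
        elements = atoms.elements
    else:
        elements = np.array([str(nm)[:1] for nm in names])
    resnames = atoms.resnames if hasattr(atoms, "resnames") else np.array(["UNK"] * n)
    resids = atoms.resids if hasattr(atoms, "resids") else np.ones(n, dtype=int)
    if hasattr(atoms, "chainIDs"):
        monomers = np.array([c if str(c).strip() else "A" for c in atoms.chainIDs])
    elif hasattr(atoms, "segids"):
        monomers = np.array([s if str(s).strip() else "A" for s in atoms.segids])
    else:
        monomers = np.array(["A"] * n)
    try:
        masses = np.asarray(atoms.masses, dtype=float)
        masses = np.where(masses > 0, masses, 1.0)
    except Exception:
        masses = np.ones(n)
    q = np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
    return ChargedStructure(
        atom_names=np.array([str(x) for x in names], dtype=object),
        elements=np.array([str(x) for x in elements], dtype=object),
        residue_names=np.array([str(x) for x in resnames], dtype=object),
        residue_ids=np.asarray(resids, dtype=int),
        monomer_labels=np.array([str(x) for x in monomers], dtype=object),
        positions=atoms.positions.astype(float),
        masses=masses,
        charges=q,
        provenance=provenance,
    )


def read_structure(path, charge_file=None) -> ChargedStructure:
    """Read a PDB structure (first model; first altloc kept).

    ``charge_file`` attaches per-atom partial charges from a sidecar; without
    it the structure is uncharged (``provenance=None``) until
    :func:`biofet.electrostatics.assign_residue_charges` runs.
    """
    mda, _ = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    s = _structure_from_universe(u)
    if charge_file is not None:
        charges = read_charge_file(charge_file, s.n_atoms)
        s = ChargedStructure(
            atom_names=s.atom_names, elements=s.elements,
            residue_names=s.residue_names, residue_ids=s.residue_ids,
            monomer_labels=s.monomer_labels, positions=s.positions,
            masses=s.masses, charges=charges, provenance="charge-file",
        )
    return s


def read_trajectory(path, topology: ChargedStructure | None = None,
                    frame_spacing_ps: float = 10.0) -> Trajectory:
    """Read a multi-model PDB or XYZ frame series.

    XYZ carries no residue/monomer labels, so a ``topology`` is required for
    it; for PDB the topology defaults to the file's own first model.
    """
    mda, _ = _import_mda()
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
    if topology is None:
        if path.suffix.lower() == ".xyz":
            raise ConfigurationError(
                "XYZ frames carry no residue labels; pass a topology structure"
            )
        topology = _structure_from_universe(u)
    if frames.shape[1] != topology.n_atoms:
        raise DataConventionError(
            f"{path}: {frames.shape[1]} atoms per frame but topology has "
            f"{topology.n_atoms}"
        )
    return Trajectory(topology=topology, frames=frames,
                      frame_spacing_ps=frame_spacing_ps)


# ---------------------------------------------------------------------------
# Charge sidecars
# ---------------------------------------------------------------------------

def write_charge_file(structure: ChargedStructure, path) -> None:
    """Write per-atom charges as ``serial charge`` lines (1-based serials)."""
    lines = [f"{i + 1} {q:.6f}" for i, q in enumerate(structure.charges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_charge_file(path, n_atoms: int) -> np.ndarray:
    """Read per-atom charges: two-column ``serial charge`` text or PQR lines."""
    charges = np.zeros(n_atoms)
    seen = np.zeros(n_atoms, dtype=bool)
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "REMARK")):
            continue
        fields = line.split()
        if fields[0] in ("ATOM", "HETATM"):  # PQR: charge is next-to-last field
            serial, q = int(fields[1]), float(fields[-2])
        elif len(fields) == 2:
            serial, q = int(fields[0]), float(fields[1])
        else:
            continue
        if not 1 <= serial <= n_atoms:
            raise DataConventionError(
                f"{path}: atom serial {serial} outside 1..{n_atoms}"
            )
        charges[serial - 1] = q
        seen[serial - 1] = True
    if not seen.any():
        raise DataConventionError(f"{path}: no charge records found")
    return charges


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    """Serialize a (nested) result object to JSON with stable key order."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
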