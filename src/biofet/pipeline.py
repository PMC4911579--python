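"""End-to-end orchestration of the two analysis tracks.

The *device track* turns baseline/signal transfer-curve pairs into extracted
figures of merit, per-device first-order decompositions and replicate
aggregates; the *structural track* turns a charged structure (plus optional
trajectory) into dipole and loop-RMSF summaries; the *bridge* compares the
Helmholtz dipole-layer prediction with the measured threshold-voltage shift
in units of the measurement's standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import device_model as dm
from .constants import DEFAULT_FOOTPRINT_NM2, DEFAULT_PROTEIN_EPS_R
from .electrostatics import (
    ChargedStructure,
    assign_residue_charges,
    dipole_moment,
    helmholtz_vt_shift,
)
from .errors import ConfigurationError, PairingError
from .trajectory_analysis import (
    DEFAULT_LOOPS,
    Trajectory,
    rmsf,
    trajectory_dipole_stats,
)

__all__ = [
    "DeviceTrackResult",
    "StructuralReport",
    "BridgeReport",
    "pair_curves",
    "run_device_track",
    "run_structural_track",
    "run_bridge",
]

EVAL_GATE_VOLTAGE = -100.0  # gate bias at which fractional changes are evaluated


@dataclass(frozen=True)
class DeviceTrackResult:
    """Per-device decoupling table plus replicate aggregates."""

    table: pd.DataFrame
    aggregates: dict
    comparison: dm.TTestResult | None = None

    def to_dict(self) -> dict:
        out = {
            "per_device": self.table.to_dict(orient="records"),
            "aggregates": {k: vars(v) for k, v in self.aggregates.items()},
        }
        if self.comparison is not None:
            out["comparison"] = vars(self.comparison)
        return out


@dataclass(frozen=True)
class StructuralReport:
    """Dipole and fluctuation summaries for one structure/trajectory."""

    static_dipoles: dict
    trajectory_dipoles: dict | None = None
    rmsf_per_loop: dict | None = None
    rmsf_per_residue: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"static_dipoles": self.static_dipoles}
        out["trajectory_dipoles"] = self.trajectory_dipoles
        out["rmsf_per_loop"] = self.rmsf_per_loop
        if self.rmsf_per_residue is not None:
            out["rmsf_per_residue"] = self.rmsf_per_residue.to_dict(orient="records")
        return out


@dataclass(frozen=True)
class BridgeReport:
    """Helmholtz prediction vs measured threshold-voltage shift.

    Magnitudes are compared (the measured shift is customarily quoted as a
    positive magnitude even when the shift itself is negative); signs are
    reported alongside.  ``agreement_sd_units`` is
    |predicted| − |measured| in units of the measurement SD.
    """

    predicted_vt_shift: float
    measured_vt_shift: float
    measured_sd: float
    agreement_sd_units: float
    within_one_sd: bool
    dipole_debye: float
    eps_r: float
    footprint_nm2: float

    def to_dict(self) -> dict:
        return dict(vars(self))


# ---------------------------------------------------------------------------
# Device track
# ---------------------------------------------------------------------------

def pair_curves(
    baselines: Sequence[dm.TransferCurve],
    signals: Sequence[dm.TransferCurve],
) -> list[tuple[dm.TransferCurve, dm.TransferCurve]]:
    """Match baseline and signal curves one-to-one on device id.

    Signal ids may carry a ``:signal`` suffix.  Raises
    :class:`PairingError` listing any unmatched ids.
    """
    def base_id(curve):
        return curve.device_id.split(":")[0]

    base_map = {base_id(c): c for c in baselines}
    sig_map = {base_id(c): c for c in signals}
    unmatched = sorted(set(base_map) ^ set(sig_map))
    if not base_map or not sig_map:
        raise PairingError("empty baseline or signal curve set")
    if unmatched:
        raise PairingError(f"unmatched baseline/signal device ids: {unmatched}")
    return [(base_map[k], sig_map[k]) for k in sorted(base_map)]


def run_device_track(
    baselines: Sequence[dm.TransferCurve],
    signals: Sequence[dm.TransferCurve],
    eval_gate_voltage: float = EVAL_GATE_VOLTAGE,
    alpha: float = 0.05,
    policy: dm.WindowPolicy | None = None,
    groups: Mapping[str, str] | None = None,
) -> DeviceTrackResult:
    """Extract figures, decouple responses and aggregate across devices.

    For each paired device the normalized current response at
    ``eval_gate_voltage``, the mobility fractional change and the
    threshold-voltage term are all measured independently, so the table also
    carries the first-order closure residual.  With ``groups`` mapping device
    ids to exactly two group labels, a Welch two-sided t-test compares the
    groups' normalized responses at level ``alpha``.
    """
    pairs = pair_curves(baselines, signals)
    rows = []
    for base, sig in pairs:
        fig0 = dm.extract_figures(base, policy)
        fig1 = dm.extract_figures(sig, policy)
        i0 = dm.current_at(base, eval_gate_voltage)
        i1 = dm.current_at(sig, eval_gate_voltage)
        delta_i = dm.normalized_response(i1, i0, device_id=base.device_id)
        delta_mu = fig1.mobility / fig0.mobility - 1.0
        delta_vt_term = (fig1.threshold_voltage - fig0.threshold_voltage) / (
            eval_gate_voltage - fig0.threshold_voltage
        )
        resp = dm.BindingResponse(
            delta_I_rel=delta_i,
            delta_mu_rel=delta_mu,
            delta_vt_term=delta_vt_term,
            eval_gate_voltage=eval_gate_voltage,
            baseline_vt=fig0.threshold_voltage,
            baseline_mu=fig0.mobility,
            device_id=base.device_id,
        )
        rows.append({
            "device_id": base.device_id,
            "baseline_vt_V": fig0.threshold_voltage,
            "signal_vt_V": fig1.threshold_voltage,
            "baseline_mu_cm2": fig0.mobility_cm2,
            "signal_mu_cm2": fig1.mobility_cm2,
            "delta_I_rel": resp.delta_I_rel,
            "delta_mu_rel": resp.delta_mu_rel,
            "delta_vt_term": resp.delta_vt_term,
            "delta_vt_V": fig1.threshold_voltage - fig0.threshold_voltage,
            "residual": resp.residual,
        })
    table = pd.DataFrame.from_records(rows)

    ids = table.device_id.tolist()
    aggregates = {
        col: dm.aggregate(table[col].to_numpy(), ids)
        for col in ("delta_I_rel", "delta_mu_rel", "delta_vt_term", "delta_vt_V")
    }

    comparison = None
    if groups:
        labels = sorted(set(groups.values()))
        if len(labels) == 2:
            a = table[table.device_id.map(groups.get) == labels[0]].delta_I_rel
            b = table[table.device_id.map(groups.get) == labels[1]].delta_I_rel
            if len(a) >= 2 and len(b) >= 2:
                comparison = dm.compare_groups(a, b, alpha=alpha)
    return DeviceTrackResult(table=table, aggregates=aggregates, comparison=comparison)


# ---------------------------------------------------------------------------
# Structural track
# ---------------------------------------------------------------------------

def run_structural_track(
    structure: ChargedStructure,
    trajectory: Trajectory | None = None,
    ph: float | None = None,
    loops=DEFAULT_LOOPS,
    trim_fraction: float = 0.10,
    monomers: Sequence[str] | None = None,
) -> StructuralReport:
    """Static (and, with a trajectory, time-averaged) dipoles and loop RMSF.

    Charges must be present on the structure, or ``ph`` given so the
    rule-based assignment can run.  Without a trajectory the RMSF section is
    reported absent (``None``).
    """
    if structure.provenance is None:
        if ph is None:
            raise ConfigurationError(
                "structure carries no charges; pass ph= for rule-based "
                "assignment or load a charge file"
            )
        structure = assign_residue_charges(structure, ph=ph)

    groups = tuple(monomers) if monomers is not None else structure.monomers
    static = {g: dipole_moment(structure, group=g).magnitude for g in groups}
    static["complex"] = dipole_moment(structure).magnitude

    if trajectory is None:
        return StructuralReport(static_dipoles=static)

    if trajectory.topology.provenance is None:
        trajectory = Trajectory(
            topology=structure,
            frames=trajectory.frames,
            frame_spacing_ps=trajectory.frame_spacing_ps,
        )
    stats = trajectory_dipole_stats(trajectory, monomers=monomers,
                                    trim_fraction=trim_fraction)
    profile = rmsf(trajectory, trim_fraction=trim_fraction, loops=loops)
    return StructuralReport(
        static_dipoles=static,
        trajectory_dipoles={"mean_D": stats.mean, "sd_D": stats.sd,
                            "per_monomer_D": stats.per_monomer},
        rmsf_per_loop=profile.per_loop,
        rmsf_per_residue=profile.per_residue,
    )


# ---------------------------------------------------------------------------
# Bridge
# ---------------------------------------------------------------------------

def run_bridge(
    dipole_debye: float,
    measured_vt_shift: float,
    measured_sd: float,
    eps_r: float = DEFAULT_PROTEIN_EPS_R,
    footprint_nm2: float = DEFAULT_FOOTPRINT_NM2,
) -> BridgeReport:
    """Compare the Helmholtz prediction against the measured V_T shift.

    The agreement is |predicted| − |measured| in SD units, passing the
    one-SD criterion when it does not exceed 1.
    """
    predicted = helmholtz_vt_shift(dipole_debye, eps_r=eps_r, area_nm2=footprint_nm2)
    gap = abs(abs(predicted) - abs(measured_vt_shift))
    if measured_sd > 0:
        agreement = gap / measured_sd
    elif gap == 0:
        agreement = 0.0
    else:
        warnings.warn(
            "measured SD is zero while prediction differs from measurement; "
            "agreement in SD units is degenerate", stacklevel=2,
        )
        agreement = float("inf")
    return BridgeReport(
        predicted_vt_shift=float(predicted),
        measured_vt_shift=float(measured_vt_shift),
        measured_sd=float(measured_sd),
        agreement_sd_units=float(agreement),
        within_one_sd=bool(agreement <= 1.0),
        dipole_debye=float(dipole_debye),
        eps_r=float(eps_r),
        footprint_nm2=float(footprint_nm2),
    )
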