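"""Transfer-curve figures of merit and first-order binding-signal decoupling.

An organic thin-film transistor (OTFT) driven in saturation obeys the
gradual-channel expression

    I_DS = (W / 2L) · C_i · μ_FET · (V_G − V_T)²

so on the accumulation branch √|I_DS| is linear in the gate voltage: the
abscissa intercept is the threshold voltage ``V_T`` and the slope yields the
field-effect mobility ``μ_FET``.  When a ligand binds to a protein layer at
the dielectric/semiconductor interface, both figures of merit respond:
``V_T`` tracks the interfacial electrostatics (dipole layer), ``μ_FET``
tracks binding-induced disorder in the transport channel.  Differentiating
the saturation expression at constant ``C_i`` decouples the normalized
current response at a fixed gate bias to first order:

    ΔI/I₀ = Δμ/μ₀ − 2·ΔV_T / (V_G − V_T0)

with the baseline figures ``μ₀`` and ``V_T0`` extracted from the pre-binding
curve.  This module implements the forward model, the extraction, the
decoupling, and the replicate statistics (mean ± one relative standard
deviation, Welch two-sided t-test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DataConventionError,
    ExtractionError,
    InsufficientReplicatesError,
    InvalidParameterError,
)

__all__ = [
    "TransferCurve",
    "DeviceFigures",
    "BindingResponse",
    "AggregateResponse",
    "TTestResult",
    "WindowPolicy",
    "saturation_current",
    "extract_figures",
    "current_at",
    "normalized_response",
    "first_order_decompose",
    "aggregate",
    "compare_groups",
    "compare_groups_from_stats",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferCurve:
    """One gate sweep of drain-source current at fixed drain bias.

    Parameters
    ----------
    gate_voltage : array of float
        Gate bias values, volts, monotone sweep.
    drain_current : array of float
        Drain-source current, amperes, same length as ``gate_voltage``.
        For p-type devices the accumulation-branch current is negative.
    drain_bias : float
        Drain-source voltage, volts.
    width, length : float
        Channel width W and length L, meters.
    c_area : float
        Gate-dielectric capacitance per unit area C_i, F/m².
    polarity : {"p", "n"}
        Carrier type; the study's devices are p-type.
    device_id : str
        Label used for pairing and error messages.
    """

    gate_voltage: np.ndarray
    drain_current: np.ndarray
    drain_bias: float
    width: float
    length: float
    c_area: float
    polarity: str = "p"
    device_id: str = ""

    def __post_init__(self) -> None:
        vg = np.asarray(self.gate_voltage, dtype=float)
        i = np.asarray(self.drain_current, dtype=float)
        object.__setattr__(self, "gate_voltage", vg)
        object.__setattr__(self, "drain_current", i)
        if vg.ndim != 1 or i.shape != vg.shape or vg.size < 4:
            raise InvalidParameterError(
                "gate_voltage and drain_current must be equal-length 1-D "
                "arrays with at least 4 points"
            )
        dv = np.diff(vg)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise InvalidParameterError("gate sweep must be strictly monotone")
        if min(self.width, self.length, self.c_area) <= 0:
            raise InvalidParameterError("W, L and C_i must be strictly positive")
        if self.polarity not in ("p", "n"):
            raise InvalidParameterError("polarity must be 'p' or 'n'")


@dataclass(frozen=True)
class DeviceFigures:
    """Extracted threshold voltage and field-effect mobility.

    ``mobility`` is in SI (m²/V·s); use :attr:`mobility_cm2` for the
    customary cm²/V·s.  ``fit_window`` is the gate-voltage interval that the
    √|I| linear fit actually used.
    """

    threshold_voltage: float
    mobility: float
    fit_window: tuple[float, float]
    fit_r2: float
    n_points: int

    @property
    def mobility_cm2(self) -> float:
        return self.mobility * 1e4

    def __post_init__(self) -> None:
        if self.mobility <= 0:
            raise InvalidParameterError("extracted mobility must be positive")
        if not 0.0 <= self.fit_r2 <= 1.0 + 1e-12:
            raise InvalidParameterError("fit_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class BindingResponse:
    """First-order decomposition of one device's binding response.

    ``delta_vt_term`` is the dimensionless ratio ΔV_T/(V_G − V_T0); the
    residual is the first-order closure gap
    ΔI/I₀ − (Δμ/μ₀ − 2·ΔV_T/(V_G − V_T0)), zero by construction whenever one
    term was solved from the other two.
    """

    delta_I_rel: float
    delta_mu_rel: float
    delta_vt_term: float
    eval_gate_voltage: float = float("nan")
    baseline_vt: float = float("nan")
    baseline_mu: float = float("nan")
    device_id: str = ""

    @property
    def residual(self) -> float:
        return self.delta_I_rel - (self.delta_mu_rel - 2.0 * self.delta_vt_term)


@dataclass(frozen=True)
class AggregateResponse:
    """Replicate summary: mean, SD and relative standard deviation (RSD)."""

    mean: float
    sd: float
    rsd: float
    n_devices: int
    member_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidParameterError("sd must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sided t-test outcome between two replicate groups."""

    statistic: float
    df: float
    pvalue: float
    alpha: float
    significant: bool


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def saturation_current(v_g, v_t, mobility, width, length, c_area, polarity="p"):
    """Saturation-regime drain current (W/2L)·C_i·μ·(V_G − V_T)².

    All arguments SI: volts, m²/V·s, meters, F/m².  The sign follows the
    carrier type (negative for p-type).  Vanishes at ``v_g == v_t``.
    """
    if min(width, length, c_area) <= 0 or mobility <= 0:
        raise InvalidParameterError(
            "width, length, c_area and mobility must be strictly positive"
        )
    v_g = np.asarray(v_g, dtype=float)
    magnitude = 0.5 * (width / length) * c_area * mobility * (v_g - v_t) ** 2
    sign = -1.0 if polarity == "p" else 1.0
    out = sign * magnitude
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Figure-of-merit extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowPolicy:
    """How the linear √|I| fit window is selected.

    The contiguous window (at least ``min_fraction`` of the accumulation
    branch and ``min_points`` points) maximizing R² is used; points with
    |I| below ``floor_multiple`` × the sub-threshold floor are excluded, and
    optionally the highest-|V_G| ``exclude_high_fraction`` of branch points
    (a blunt guard against contact-resistance roll-off; the R² criterion
    normally rejects the roll-off region on its own).
    """

    min_fraction: float = 0.30
    min_points: int = 4
    floor_multiple: float = 3.0
    exclude_high_fraction: float = 0.0
    min_r2: float = 0.90


def extract_figures(curve: TransferCurve, policy: WindowPolicy | None = None) -> DeviceFigures:
    """Extract (V_T, μ_FET) from a transfer curve by the √|I| linear fit.

    For p-type devices the fit runs on |I_DS| with the gate axis flipped so
    the accumulation branch always has positive slope; the reported V_T is
    signed in the original convention.

    Raises
    ------
    ExtractionError
        If no window meets the linearity criterion (R² ≥ policy.min_r2).
    DataConventionError
        If currents on the fitted branch change sign.
    """
    policy = policy or WindowPolicy()
    flip = -1.0 if curve.polarity == "p" else 1.0
    order = np.argsort(flip * curve.gate_voltage)
    x = (flip * curve.gate_voltage)[order]
    i_raw = curve.drain_current[order]
    i_abs = np.abs(i_raw)

    # Sub-threshold floor from the smallest-|I| points (leakage estimate).
    floor = float(np.median(np.sort(i_abs)[: max(3, i_abs.size // 4)]))
    keep = i_abs > (policy.floor_multiple * floor if floor > 0 else 0.0)
    x, i_raw, i_abs = x[keep], i_raw[keep], i_abs[keep]

    if policy.exclude_high_fraction > 0 and x.size:
        n_cut = int(math.floor(policy.exclude_high_fraction * x.size))
        if n_cut:
            x, i_raw, i_abs = x[:-n_cut], i_raw[:-n_cut], i_abs[:-n_cut]

    m = x.size
    if m < policy.min_points:
        raise ExtractionError(
            f"device {curve.device_id!r}: only {m} accumulation-branch points "
            f"above the sub-threshold floor (need >= {policy.min_points})"
        )

    y = np.sqrt(i_abs)
    w_min = max(policy.min_points, int(math.ceil(policy.min_fraction * m)))
    best = None
    for a in range(0, m - w_min + 1):
        for b in range(a + w_min, m + 1):
            xv, yv = x[a:b], y[a:b]
            slope, intercept = np.polyfit(xv, yv, 1)
            if slope <= 0:
                continue
            resid = yv - (slope * xv + intercept)
            ss_tot = float(np.sum((yv - yv.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
            # Round so numerically-perfect windows tie and the longest wins.
            key = (round(r2, 12), b - a, -x[b - 1])
            if best is None or key > best[0]:
                best = (key, a, b, slope, intercept, r2)
    if best is None:
        raise ExtractionError(
            f"device {curve.device_id!r}: no window with positive-slope "
            "sqrt(|I|) fit on the accumulation branch"
        )
    _, a, b, slope, intercept, r2 = best
    if r2 < policy.min_r2:
        raise ExtractionError(
            f"device {curve.device_id!r}: best fit window R²={r2:.4f} below "
            f"the linearity criterion R² >= {policy.min_r2}"
        )
    win_raw = i_raw[a:b]
    if np.any(win_raw > 0) and np.any(win_raw < 0):
        raise DataConventionError(
            f"device {curve.device_id!r}: drain currents change sign on the "
            "fitted branch; check the polarity/sign convention"
        )

    x0 = -intercept / slope  # abscissa intercept on the (possibly flipped) axis
    v_t = flip * x0
    mobility = slope**2 * 2.0 * curve.length / (curve.width * curve.c_area)
    vg_window = flip * x[a:b]
    return DeviceFigures(
        threshold_voltage=float(v_t),
        mobility=float(mobility),
        fit_window=(float(vg_window.min()), float(vg_window.max())),
        fit_r2=min(float(r2), 1.0),
        n_points=b - a,
    )


def current_at(curve: TransferCurve, v_g: float) -> float:
    """Drain current at gate bias ``v_g``, linearly interpolated on the sweep."""
    order = np.argsort(curve.gate_voltage)
    return float(
        np.interp(v_g, curve.gate_voltage[order], curve.drain_current[order])
    )


# ---------------------------------------------------------------------------
# Response normalization and first-order decoupling
# ---------------------------------------------------------------------------

def normalized_response(i_signal: float, i_baseline: float, device_id: str = "") -> float:
    """Normalized current response (I − I₀)/I₀ at a fixed gate bias.

    Both currents keep their sign convention, so a decrease in current
    magnitude yields a negative response regardless of carrier type.
    """
    if i_baseline == 0:
        raise DataConventionError(
            f"device {device_id!r}: baseline current is zero, "
            "normalized response undefined"
        )
    return (i_signal - i_baseline) / i_baseline


def first_order_decompose(
    delta_I_rel: float | None = None,
    delta_mu_rel: float | None = None,
    delta_vt_term: float | None = None,
    *,
    eval_gate_voltage: float = float("nan"),
    baseline_vt: float = float("nan"),
    baseline_mu: float = float("nan"),
    device_id: str = "",
) -> BindingResponse:
    """Solve the first-order relation ΔI/I₀ = Δμ/μ₀ − 2·ΔV_T/(V_G − V_T0).

    Supply exactly two of the three terms to solve for the third.  Supplying
    all three (each measured independently) leaves the closure gap in
    :attr:`BindingResponse.residual` instead of solving anything.
    """
    known = [delta_I_rel is not None, delta_mu_rel is not None, delta_vt_term is not None]
    n_known = sum(known)
    if n_known < 2:
        raise InvalidParameterError(
            "supply at least two of delta_I_rel, delta_mu_rel, delta_vt_term"
        )
    if n_known == 2:
        if delta_I_rel is None:
            delta_I_rel = delta_mu_rel - 2.0 * delta_vt_term
        elif delta_mu_rel is None:
            delta_mu_rel = delta_I_rel + 2.0 * delta_vt_term
        else:
            delta_vt_term = (delta_mu_rel - delta_I_rel) / 2.0
    return BindingResponse(
        delta_I_rel=float(delta_I_rel),
        delta_mu_rel=float(delta_mu_rel),
        delta_vt_term=float(delta_vt_term),
        eval_gate_voltage=eval_gate_voltage,
        baseline_vt=baseline_vt,
        baseline_mu=baseline_mu,
        device_id=device_id,
    )


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

def aggregate(values: Sequence[float], member_ids: Sequence[str] | None = None) -> AggregateResponse:
    """Mean, SD (ddof=1) and relative standard deviation over replicates."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise InsufficientReplicatesError("aggregate requires at least one value")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    rsd = sd / abs(mean) if mean != 0 else float("inf") if sd > 0 else 0.0
    ids = tuple(member_ids) if member_ids is not None else ()
    return AggregateResponse(mean=mean, sd=sd, rsd=rsd, n_devices=int(v.size), member_ids=ids)


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den if den > 0 else float(n1 + n2 - 2)


def compare_groups(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Welch (unequal-variance) two-sided t-test between two replicate groups."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError("each group needs n >= 2 for the t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = a.mean() == b.mean()
        return TTestResult(0.0 if equal else float("inf"), float(a.size + b.size - 2),
                           1.0 if equal else 0.0, alpha, not equal)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = _welch_df(a.var(ddof=1), a.size, b.var(ddof=1), b.size)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), df, p, alpha, p < alpha)


def compare_groups_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    alpha: float = 0.05,
) -> TTestResult:
    """Welch t-test from summary statistics (mean, SD, n) of each group."""
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("each group needs n >= 2 for the t-test")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    df = _welch_df(sd1**2, n1, sd2**2, n2)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), df, p, alpha, p < alpha)
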