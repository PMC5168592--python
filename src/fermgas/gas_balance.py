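"""Headspace gas mass balance of a N2-sparged batch bioreactor.

A fermenting culture produces H2 and CO2 into a headspace that is continuously
swept by an N2 carrier stream.  Writing a material balance for each of the
three gases over the dry headspace volume V = V_HR - V_Steam gives, per gas X
in {N2, CO2, H2},

    d p_X_out / dt = (Q_X * p_X - Q_T_out * p_X_out) / V

where p_X_out is the outlet fraction of X (% of total pressure), p_X = 100 %
is the purity of each source stream, Q_X the volumetric flow of X entering the
headspace (carrier for N2, biological production for H2/CO2, all at headspace
temperature), and Q_T_out = Q_N2 + Q_CO2 + Q_H2 the total outflow (isobaric
headspace).  The outlet fractions sum to 100 % at all times.

This module provides both directions of that model:

* the forward problem — :func:`simulate_headspace` integrates the ODEs for a
  known production history, optionally under the closed-loop carrier-flow
  controller that holds the outlet H2 fraction at a setpoint (5 % by default,
  i.e. 35 mbar, below the growth-inhibitory partial pressure);
* the inverse problem — :func:`reconstruct_production` recovers the biological
  H2 and CO2 production flows from recorded outlet fractions and carrier-flow
  data, and integrates them to cumulative mmol per litre of culture.

Flows are handled in mL/min at headspace temperature internally; time is hours
at the interfaces.  The carrier mass-flow meter reads at a reference
temperature, hence :func:`correct_flow_to_headspace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.interpolate import interp1d

from .carbonate import CarbonateConstants, speciate
from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "GAS_CONSTANT_L_BAR",
    "HeadspaceConfig",
    "OutletGasSeries",
    "ProductionSeries",
    "ControlAction",
    "correct_flow_to_headspace",
    "steam_volume_antoine",
    "control_n2_flow",
    "closed_loop_n2_policy",
    "simulate_headspace",
    "reconstruct_production",
    "total_dissolved_co2_correction",
]

#: Ideal-gas constant in L bar mol-1 K-1.
GAS_CONSTANT_L_BAR = 0.0831446

# Antoine constants for water, P_sat in mmHg with T in degC, valid 1-100 degC.
_ANTOINE_A = 8.07131
_ANTOINE_B = 1730.63
_ANTOINE_C = 233.426
_MMHG_PER_BAR = 750.062


@dataclass(frozen=True)
class HeadspaceConfig:
    """Fixed geometry, temperatures and controller settings of the reactor.

    Defaults describe a 2.3 L vessel with 1.5 L working volume: 960 mL
    headspace of which a fixed 320 mL is attributed to water vapour, a
    headspace at 69 degC (median during a run), a carrier mass-flow meter
    referenced to 20 degC, the culture at 80 degC, and an isobaric headspace
    at 1 bar.  The off-gas controller targets 5 % H2 in the outlet and the
    emptying phase of a fermentation cycle triggers when the regulated carrier
    flow falls below 15 mL/min.
    """

    v_headspace_mL: float = 960.0
    v_steam_mL: float = 320.0
    t_head_C: float = 69.0
    t_ref_C: float = 20.0
    t_liquid_C: float = 80.0
    p_total_bar: float = 1.0
    h2_setpoint_pct: float = 5.0
    empty_trigger_flow_mL_min: float = 15.0
    initial_n2_flow_mL_min: float = 10.0
    liquid_volume_L: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.v_steam_mL < self.v_headspace_mL:
            raise InvalidConfigError(
                "need 0 < v_steam_mL < v_headspace_mL, got "
                f"{self.v_steam_mL} vs {self.v_headspace_mL}"
            )
        for name in (
            "p_total_bar",
            "empty_trigger_flow_mL_min",
            "initial_n2_flow_mL_min",
            "liquid_volume_L",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if not 0 < self.h2_setpoint_pct < 100:
            raise InvalidConfigError(
                f"h2_setpoint_pct must be in (0, 100), got {self.h2_setpoint_pct}"
            )

    @property
    def dry_headspace_mL(self) -> float:
        """Headspace volume available to dry gas, V_HR - V_Steam."""
        return self.v_headspace_mL - self.v_steam_mL

    @property
    def mmol_per_mL_gas(self) -> float:
        """Moles per mL of gas at headspace temperature and total pressure (mmol/mL)."""
        t_K = 273.15 + self.t_head_C
        return self.p_total_bar / (GAS_CONSTANT_L_BAR * t_K)  # mol/L == mmol/mL


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class OutletGasSeries:
    """Recorded (or simulated) off-gas composition and carrier-flow history.

    Attributes
    ----------
    time_h : array
        Sample times, hours, strictly increasing.
    p_n2, p_h2, p_co2 : array
        Outlet fractions in % of total pressure; sum to 100 within
        ``sum_tolerance_pct``.
    q_n2_ref : array
        Carrier (N2) flow as read by the mass-flow meter at its reference
        temperature, mL/min, aligned with ``time_h``.
    ph : array or None
        Optional culture pH record, used by the dissolved-CO2 correction.
    """

    time_h: np.ndarray
    p_n2: np.ndarray
    p_h2: np.ndarray
    p_co2: np.ndarray
    q_n2_ref: np.ndarray
    ph: np.ndarray | None = None
    sum_tolerance_pct: float = 2.0

    def __post_init__(self) -> None:
        t = _as_1d(self.time_h, "time_h")
        object.__setattr__(self, "time_h", t)
        if t.size < 2:
            raise InvalidInputError("OutletGasSeries needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time_h must be strictly increasing")
        for name in ("p_n2", "p_h2", "p_co2", "q_n2_ref"):
            arr = _as_1d(getattr(self, name), name)
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape:
                raise InvalidInputError(f"{name} must align with time_h")
        for name in ("p_n2", "p_h2", "p_co2"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 100):
                raise InvalidInputError(f"{name} fractions must lie in [0, 100] %")
        if np.any(self.q_n2_ref < 0):
            raise InvalidInputError("q_n2_ref must be >= 0")
        total = self.p_n2 + self.p_h2 + self.p_co2
        worst = float(np.max(np.abs(total - 100.0)))
        if worst > self.sum_tolerance_pct:
            raise InvalidInputError(
                f"outlet fractions sum to 100 +/- {self.sum_tolerance_pct} % "
                f"violated (worst deviation {worst:.3g} %)"
            )
        if self.ph is not None:
            ph = _as_1d(self.ph, "ph")
            object.__setattr__(self, "ph", ph)
            if ph.shape != t.shape:
                raise InvalidInputError("ph must align with time_h")


@dataclass(frozen=True)
class ProductionSeries:
    """Biological gas production history.

    ``q_h2``/``q_co2`` are volumetric production flows at headspace
    temperature (mL/min); ``cum_h2``/``cum_co2`` the cumulative production in
    mmol per litre of culture liquid.  When produced by
    :func:`reconstruct_production`, the unclipped flows are retained in
    ``raw_q_h2``/``raw_q_co2`` for diagnostics (measurement noise can drive
    the per-sample inversion slightly negative).
    """

    time_h: np.ndarray
    q_h2: np.ndarray
    q_co2: np.ndarray
    cum_h2: np.ndarray | None = None
    cum_co2: np.ndarray | None = None
    raw_q_h2: np.ndarray | None = field(default=None, repr=False)
    raw_q_co2: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        t = _as_1d(self.time_h, "time_h")
        object.__setattr__(self, "time_h", t)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time_h must be strictly increasing")
        for name in ("q_h2", "q_co2", "cum_h2", "cum_co2", "raw_q_h2", "raw_q_co2"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = _as_1d(arr, name)
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape:
                raise InvalidInputError(f"{name} must align with time_h")
        for name in ("q_h2", "q_co2"):
            if np.any(getattr(self, name) < 0):
                raise InvalidInputError(f"{name} must be >= 0 (clip before constructing)")
        for name in ("cum_h2", "cum_co2"):
            arr = getattr(self, name)
            if arr is not None and np.any(np.diff(arr) < -1e-9):
                raise InvalidInputError(f"{name} must be non-decreasing")

    def total_flow(self, q_n2: np.ndarray) -> np.ndarray:
        """Total outflow Q_T = Q_N2 + Q_CO2 + Q_H2 for a given carrier history."""
        return np.asarray(q_n2, dtype=float) + self.q_co2 + self.q_h2


def correct_flow_to_headspace(flow_at_ref, config: HeadspaceConfig | None = None):
    """Convert a mass-flow-meter reading to volumetric flow at headspace temperature.

    Isobaric ideal-gas expansion: flow * (273 + T_head) / (273 + T_ref).
    Accepts scalars or arrays (mL/min).
    """
    if config is None:
        config = HeadspaceConfig()
    flow = np.asarray(flow_at_ref, dtype=float)
    if np.any(flow < 0):
        raise InvalidInputError("carrier flow must be >= 0")
    factor = (273.0 + config.t_head_C) / (273.0 + config.t_ref_C)
    out = flow * factor
    return float(out) if np.isscalar(flow_at_ref) else out


def correct_flow_to_reference(flow_at_head, config: HeadspaceConfig | None = None):
    """Inverse of :func:`correct_flow_to_headspace`."""
    if config is None:
        config = HeadspaceConfig()
    flow = np.asarray(flow_at_head, dtype=float)
    if np.any(flow < 0):
        raise InvalidInputError("carrier flow must be >= 0")
    factor = (273.0 + config.t_ref_C) / (273.0 + config.t_head_C)
    out = flow * factor
    return float(out) if np.isscalar(flow_at_head) else out


def steam_volume_antoine(t_C: float, config: HeadspaceConfig | None = None) -> float:
    """Water-vapour volume of the headspace from the Antoine equation (diagnostic).

    Evaluates the saturation vapour pressure of water at ``t_C`` and returns
    the corresponding fraction of the headspace volume,
    ``min(P_sat / P_total, 1) * V_HR`` in mL.  The pipeline default keeps the
    fixed ``v_steam_mL`` of :class:`HeadspaceConfig`; this function exists to
    check that choice (standard Antoine constants give ~286 mL at 69 degC,
    somewhat below the 320 mL default).
    """
    if config is None:
        config = HeadspaceConfig()
    if not 0 < t_C < 100:
        raise InvalidInputError(f"temperature must be in (0, 100) degC, got {t_C}")
    p_sat_bar = 10.0 ** (_ANTOINE_A - _ANTOINE_B / (t_C + _ANTOINE_C)) / _MMHG_PER_BAR
    frac = min(p_sat_bar / config.p_total_bar, 1.0)
    return frac * config.v_headspace_mL


class ControlAction(NamedTuple):
    """Carrier-flow command with the reactor-emptying flag."""

    flow_mL_min: float
    empty_triggered: bool


def control_n2_flow(
    q_h2: float,
    q_co2: float,
    config: HeadspaceConfig | None = None,
    min_flow: float | None = None,
) -> ControlAction:
    """Steady-state feedforward carrier flow holding the outlet H2 setpoint.

    At steady state the outlet H2 fraction is Q_H2 / (Q_N2 + Q_CO2 + Q_H2),
    so the carrier flow achieving setpoint s is

        Q_N2 = Q_H2 * (100 - s) / s - Q_CO2,

    floored at ``min_flow`` (default: the initial carrier flow).  The emptying
    flag is raised when the commanded flow falls below the configured trigger
    threshold — at the end of a fermentation the weakening H2 production drags
    the regulated carrier flow down, which is how the process detects glucose
    exhaustion.  All flows in mL/min at headspace temperature.
    """
    if config is None:
        config = HeadspaceConfig()
    if q_h2 < 0 or q_co2 < 0:
        raise InvalidInputError("production flows must be >= 0")
    s = config.h2_setpoint_pct
    if s <= 0:
        raise InvalidConfigError("h2_setpoint_pct must be > 0")
    if min_flow is None:
        min_flow = config.initial_n2_flow_mL_min
    raw = q_h2 * (100.0 - s) / s - q_co2
    flow = max(raw, min_flow)
    return ControlAction(flow, flow < config.empty_trigger_flow_mL_min)


def closed_loop_n2_policy(
    production: ProductionSeries,
    config: HeadspaceConfig | None = None,
    smoothing_min: float = 5.0,
) -> np.ndarray:
    """Carrier-flow history of the setpoint controller along a production series.

    Applies :func:`control_n2_flow` sample-by-sample and smooths the command
    with a first-order filter (time constant ``smoothing_min`` minutes),
    mimicking the sluggishness of a real flow regulation without inventing
    feedback gains.  Returns Q_N2 at headspace temperature, aligned with
    ``production.time_h``.
    """
    if config is None:
        config = HeadspaceConfig()
    raw = np.array(
        [
            control_n2_flow(qh, qc, config).flow_mL_min
            for qh, qc in zip(production.q_h2, production.q_co2)
        ]
    )
    if smoothing_min <= 0:
        return raw
    out = np.empty_like(raw)
    out[0] = raw[0]
    t_min = production.time_h * 60.0
    for i in range(1, raw.size):
        alpha = 1.0 - np.exp(-(t_min[i] - t_min[i - 1]) / smoothing_min)
        out[i] = out[i - 1] + alpha * (raw[i] - out[i - 1])
    return out


def _zoh(time_h: np.ndarray, values: np.ndarray) -> Callable[[float], float]:
    """Zero-order-hold interpolant (rates are piecewise constant between samples)."""
    return interp1d(
        time_h,
        values,
        kind="previous",
        bounds_error=False,
        fill_value=(values[0], values[-1]),
    )


def simulate_headspace(
    production: ProductionSeries,
    n2_flow_policy,
    config: HeadspaceConfig | None = None,
    initial_fractions: Sequence[float] = (100.0, 0.0, 0.0),
    rtol: float = 1e-8,
    ph: np.ndarray | None = None,
) -> OutletGasSeries:
    """Integrate the headspace material balances for a known production history.

    Parameters
    ----------
    production : ProductionSeries
        Biological H2/CO2 flows (mL/min at headspace temperature) on a time
        grid finer than the headspace residence time V / Q_T.
    n2_flow_policy : float, array or callable
        Carrier flow at headspace temperature: a constant, an array aligned
        with ``production.time_h`` (zero-order hold between samples, e.g. the
        output of :func:`closed_loop_n2_policy`), or a callable of time in
        hours.
    initial_fractions : (p_n2, p_h2, p_co2)
        Outlet composition at the first sample, %; must sum to 100.

    Returns
    -------
    OutletGasSeries
        Outlet fractions at the production sample times, with the carrier
        record converted back to meter-reference temperature.
    """
    if config is None:
        config = HeadspaceConfig()
    t = production.time_h
    init = np.asarray(initial_fractions, dtype=float)
    if init.shape != (3,) or abs(init.sum() - 100.0) > 1e-6 or np.any(init < 0):
        raise InvalidInputError("initial_fractions must be 3 non-negative values summing to 100")

    q_h2_of = _zoh(t, production.q_h2)
    q_co2_of = _zoh(t, production.q_co2)
    if callable(n2_flow_policy):
        q_n2_of = n2_flow_policy
    elif np.isscalar(n2_flow_policy):
        const = float(n2_flow_policy)
        if const < 0:
            raise InvalidInputError("carrier flow must be >= 0")
        q_n2_of = lambda _t: const  # noqa: E731
    else:
        arr = _as_1d(n2_flow_policy, "n2_flow_policy")
        if arr.shape != t.shape:
            raise InvalidInputError("n2_flow_policy array must align with production.time_h")
        q_n2_of = _zoh(t, arr)

    v = config.dry_headspace_mL
    t_min = (t - t[0]) * 60.0

    def rhs(tm: float, p: np.ndarray) -> np.ndarray:
        th = t[0] + tm / 60.0
        q = np.array([float(q_n2_of(th)), float(q_h2_of(th)), float(q_co2_of(th))])
        q_tot = q.sum()
        if q_tot <= 0:
            raise InvalidInputError("total gas flow is zero: headspace state undefined")
        return (q * 100.0 - q_tot * p) / v

    # max_step below the sampling interval so piecewise-constant inputs are seen
    max_step = max(float(np.min(np.diff(t_min))), 1e-3)
    sol = solve_ivp(
        rhs,
        (t_min[0], t_min[-1]),
        init,
        t_eval=t_min,
        method="LSODA",
        rtol=rtol,
        atol=1e-10,
        max_step=max_step,
    )
    if not sol.success:  # pragma: no cover - integrator failure is exceptional
        raise RuntimeError(f"headspace integration failed: {sol.message}")
    p_n2, p_h2, p_co2 = sol.y
    q_n2 = np.array([float(q_n2_of(th)) for th in t])
    return OutletGasSeries(
        time_h=t.copy(),
        p_n2=np.clip(p_n2, 0.0, 100.0),
        p_h2=np.clip(p_h2, 0.0, 100.0),
        p_co2=np.clip(p_co2, 0.0, 100.0),
        q_n2_ref=correct_flow_to_reference(q_n2, config),
        ph=None if ph is None else np.asarray(ph, dtype=float),
        sum_tolerance_pct=0.01,
    )


def reconstruct_production(
    outlet: OutletGasSeries,
    config: HeadspaceConfig | None = None,
    qss_tolerance_pct: float = 0.005,
    clip_negative: bool = True,
) -> ProductionSeries:
    """Invert the headspace balances: recover biological H2/CO2 production.

    Per sample, with the temperature-corrected carrier flow Q_N2 known, the N2
    balance is solved for the total outflow,

        Q_T = (100 * Q_N2 - V * dp_N2/dt) / p_N2_out,

    and the H2/CO2 balances for the production flows,

        Q_X = (V * dp_X/dt + Q_T * p_X_out) / 100.

    Time derivatives are central finite differences on the sample grid.  When
    the accumulation term is small — |dp/dt| * V / Q_T below
    ``qss_tolerance_pct`` (% of total pressure) — the quasi-steady-state
    solution (derivative dropped) is used instead, which is markedly less
    noise-sensitive.  The dropped term is bounded by
    ``qss_tolerance_pct * Q_T / 100`` in flow units, so the default keeps the
    switchover bias well under 1 % of typical production flows; for noisy,
    coarsely sampled records a larger tolerance (e.g. 0.1) trades accuracy
    for smoothness.

    Negative flows produced by measurement noise are clipped to zero before
    integration (raw values kept on the result).  Flows are converted to molar
    rates by the ideal-gas relation at headspace temperature and total
    pressure and integrated (trapezoid) to cumulative mmol per litre of
    culture liquid.
    """
    if config is None:
        config = HeadspaceConfig()
    if np.any(outlet.p_n2 <= 0):
        raise InvalidInputError("p_n2 = 0 makes the N2-balance inversion singular")
    t_min = outlet.time_h * 60.0
    v = config.dry_headspace_mL
    q_n2 = correct_flow_to_headspace(outlet.q_n2_ref, config)

    dpdt = {
        name: np.gradient(getattr(outlet, name), t_min)
        for name in ("p_n2", "p_h2", "p_co2")
    }
    # quasi-steady-state total flow, used both as fallback and as the scale
    # against which the accumulation term is judged
    q_t_qss = 100.0 * q_n2 / outlet.p_n2
    with np.errstate(divide="ignore", invalid="ignore"):
        accum_scale = v / np.where(q_t_qss > 0, q_t_qss, np.inf)

    use_qss_n2 = np.abs(dpdt["p_n2"]) * accum_scale < qss_tolerance_pct
    q_t = np.where(use_qss_n2, q_t_qss, (100.0 * q_n2 - v * dpdt["p_n2"]) / outlet.p_n2)

    flows = {}
    for name in ("p_h2", "p_co2"):
        frac = getattr(outlet, name)
        use_qss = np.abs(dpdt[name]) * accum_scale < qss_tolerance_pct
        full = (v * dpdt[name] + q_t * frac) / 100.0
        qss = q_t * frac / 100.0
        flows[name] = np.where(use_qss, qss, full)

    raw_h2, raw_co2 = flows["p_h2"], flows["p_co2"]
    q_h2 = np.clip(raw_h2, 0.0, None) if clip_negative else raw_h2
    q_co2 = np.clip(raw_co2, 0.0, None) if clip_negative else raw_co2

    mmol_per_mL = config.mmol_per_mL_gas
    scale = mmol_per_mL / config.liquid_volume_L  # mmol L-1 per (mL min-1 . min)
    cum_h2 = cumulative_trapezoid(q_h2 * scale, t_min, initial=0.0)
    cum_co2 = cumulative_trapezoid(q_co2 * scale, t_min, initial=0.0)
    return ProductionSeries(
        time_h=outlet.time_h.copy(),
        q_h2=q_h2,
        q_co2=q_co2,
        cum_h2=cum_h2,
        cum_co2=cum_co2,
        raw_q_h2=raw_h2,
        raw_q_co2=raw_co2,
    )


def total_dissolved_co2_correction(
    pco2_bar: float,
    ph: float,
    liquid_volume_L: float | None = None,
    constants: CarbonateConstants | None = None,
    config: HeadspaceConfig | None = None,
) -> float:
    """Dissolved-CO2 inventory of the liquid phase, mmol.

    The off-gas balance only sees CO2 that left the liquid; at the regulated
    culture pH a substantial amount stays dissolved as CO2(aq)/HCO3-/CO3--.
    This returns that inventory — total dissolved inorganic carbon from
    :func:`fermgas.carbonate.speciate` times the working liquid volume — to be
    added to the cumulative gas-phase CO2.  By default applied once at the end
    of a run (the inventory at run end), but callers may evaluate it along a
    pH/pCO2 record for a continuous correction.
    """
    if config is None:
        config = HeadspaceConfig()
    if liquid_volume_L is None:
        liquid_volume_L = config.liquid_volume_L
    if liquid_volume_L <= 0:
        raise InvalidInputError("liquid volume must be > 0")
    spec = speciate(pco2_bar, ph, constants)
    return spec.total * liquid_volume_L * 1000.0
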