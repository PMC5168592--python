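"""Fermentation accounting: recoveries, yields, productivities, sulfur budget.

Derived quantities for glucose dark fermentation by *Thermotoga maritima*,
where glucose is fermented mainly to acetate, H2 and CO2 (ideally 1 glucose ->
2 acetate + 4 H2 + 2 CO2, the Thauer limit), with lactate, L-alanine and
extracellular polysaccharides (EPS, measured in glucose equivalents) as side
products and cell dry weight carrying 50 % carbon.

All window-based quantities are differences of interpolated values between two
times of a :class:`FermentationRun`.  Two window conventions recur in batch
studies and both are supported: from inoculation (t0) to a sampling time, and
over the growth phase proper (t1 to t2).  Specific rates divide the volumetric
rate by the logarithmic-mean biomass, the averaging consistent with a constant
specific rate during exponential growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import InvalidInputError

__all__ = [
    "ATOMIC_MASS",
    "StoichiometryProfile",
    "PhaseMarkers",
    "FermentationRun",
    "YieldReport",
    "SulfurBudget",
    "ThiosulfateYieldFit",
    "VolumetricRates",
    "SpecificRates",
    "od_to_dry_weight",
    "carbon_recovery",
    "volumetric_rates",
    "specific_rates",
    "molar_yields",
    "yield_on_thiosulfate",
    "sulfur_budget",
    "thiosulfate_detox_capacity",
    "log_mean",
]

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06}


@dataclass(frozen=True)
class StoichiometryProfile:
    """Carbon bookkeeping and elemental-composition constants.

    ``carbon_atoms`` counts carbons per mole of each measured pool (EPS in
    glucose equivalents).  ``cell_formula`` is the elemental composition of
    the biomass per carbon, C1 H1.6 O0.6 N0.2 S0.005; its formula-unit mass
    (~26.18 g per C-mol) converts cell dry weight to elemental inventories.
    """

    carbon_atoms: dict = field(
        default_factory=lambda: {
            "glucose": 6,
            "acetate": 2,
            "lactate": 3,
            "alanine": 3,
            "eps_glucose_equiv": 6,
            "co2": 1,
        }
    )
    cell_carbon_fraction: float = 0.5  # g C per g dry cells
    h2_per_acetate: float = 2.0
    h2_per_thiosulfate: float = 4.0
    s_per_thiosulfate: float = 2.0
    ye_sulfur_mmol_per_g: float = 0.07  # organic S (cystine + methionine) per g yeast extract
    cell_formula: dict = field(
        default_factory=lambda: {"C": 1.0, "H": 1.6, "O": 0.6, "N": 0.2, "S": 0.005}
    )

    @property
    def cell_formula_mass(self) -> float:
        """Mass of one C-mol of biomass, g."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.cell_formula.items())

    @property
    def cell_sulfur_per_mg(self) -> float:
        """mmol S per mg cell dry weight."""
        return self.cell_formula["S"] / self.cell_formula_mass


DEFAULT_STOICHIOMETRY = StoichiometryProfile()


class PhaseMarkers(NamedTuple):
    """Run phase boundaries, hours: start, growth onset, growth end, run end."""

    t0: float
    t1: float
    t2: float
    t3: float


@dataclass(frozen=True)
class FermentationRun:
    """Liquid-phase time series of one batch fermentation.

    Concentrations are mmol/L except ``cells`` (mg dry weight per L).
    ``glucose_consumed`` is cumulative from t0.  Columns that were not assayed
    may be NaN.  ``co2_mode`` selects how the carbon balance obtains CO2:
    ``"measured"`` uses the ``co2`` column (off-gas reconstruction plus the
    dissolved inventory), ``"acetate_stoichiometric"`` assumes one CO2 per
    acetate — the convention for serum-bottle cultures with no off-gas train.
    """

    time_h: np.ndarray
    cells: np.ndarray
    glucose_consumed: np.ndarray
    lactate: np.ndarray
    acetate: np.ndarray
    h2: np.ndarray
    co2: np.ndarray | None = None
    alanine: np.ndarray | None = None
    eps_glucose_equiv: np.ndarray | None = None
    thiosulfate_initial_mM: float = 0.0
    yeast_extract_g_L: float = 1.0
    phases: PhaseMarkers | None = None
    co2_mode: str = "measured"
    label: str = ""

    _COLUMNS = (
        "cells",
        "glucose_consumed",
        "lactate",
        "acetate",
        "h2",
        "co2",
        "alanine",
        "eps_glucose_equiv",
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        object.__setattr__(self, "time_h", t)
        if t.ndim != 1 or t.size < 2:
            raise InvalidInputError("time_h must be 1-D with at least two samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time_h must be strictly increasing")
        for name in self._COLUMNS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape:
                raise InvalidInputError(f"{name} must align with time_h")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise InvalidInputError(f"{name} has negative values")
        g = self.glucose_consumed
        finite = np.isfinite(g)
        if np.any(np.diff(g[finite]) < -1e-9):
            raise InvalidInputError("glucose_consumed must be non-decreasing")
        if self.co2_mode not in ("measured", "acetate_stoichiometric"):
            raise InvalidInputError(f"unknown co2_mode {self.co2_mode!r}")
        if self.co2_mode == "measured" and self.co2 is None:
            raise InvalidInputError("co2_mode='measured' requires a co2 column")
        if self.thiosulfate_initial_mM < 0 or self.yeast_extract_g_L < 0:
            raise InvalidInputError("medium composition must be >= 0")
        if self.phases is not None:
            p = PhaseMarkers(*self.phases)
            object.__setattr__(self, "phases", p)
            if not (p.t0 <= p.t1 < p.t2 <= p.t3):
                raise InvalidInputError(f"phase markers must satisfy t0 <= t1 < t2 <= t3, got {p}")

    # -- window helpers -----------------------------------------------------

    def resolve_window(self, window) -> tuple[float, float]:
        """Resolve a window spec to (t_start, t_end) in hours.

        ``window`` may be an explicit ``(t_start, t_end)`` pair or one of the
        named conventions ``"growth"`` (t1 -> t2), ``"to_t2"`` (t0 -> t2) and
        ``"total"`` (t0 -> t3); the named ones require phase markers.
        """
        if isinstance(window, str):
            if self.phases is None:
                raise InvalidInputError(f"named window {window!r} requires phase markers")
            p = self.phases
            named = {"growth": (p.t1, p.t2), "to_t2": (p.t0, p.t2), "total": (p.t0, p.t3)}
            try:
                return named[window]
            except KeyError:
                raise InvalidInputError(f"unknown window {window!r}") from None
        a, b = float(window[0]), float(window[1])
        if b <= a:
            raise InvalidInputError(f"window must have positive duration, got ({a}, {b})")
        return a, b

    def value_at(self, column: str, t: float) -> float:
        """Linearly interpolated value of ``column`` at time ``t`` (hours)."""
        arr = getattr(self, column)
        if arr is None:
            raise InvalidInputError(f"run has no {column!r} data")
        finite = np.isfinite(arr)
        if not finite.any():
            raise InvalidInputError(f"column {column!r} is all-NaN")
        return float(np.interp(t, self.time_h[finite], arr[finite]))

    def delta(self, column: str, window) -> float:
        """Change of ``column`` over ``window``."""
        a, b = self.resolve_window(window)
        return self.value_at(column, b) - self.value_at(column, a)


class VolumetricRates(NamedTuple):
    """Volumetric productivities over a window."""

    q_cells_mg_L_h: float
    q_glucose_mM_h: float
    q_h2_mM_h: float


class SpecificRates(NamedTuple):
    """Per-gram-of-cells rates over a window (mmol g-1 h-1)."""

    q_glucose: float
    q_h2: float


@dataclass(frozen=True)
class YieldReport:
    """Derived accounting summary of one run over one window."""

    window_h: tuple[float, float]
    c1_recovery_pct: float | None
    c2_recovery_pct: float | None
    h2_per_acetate: float | None
    acetate_per_glucose: float | None
    lactate_per_glucose: float | None
    h2_per_glucose: float | None
    alanine_per_glucose: float | None
    eps_per_glucose: float | None
    cells_per_glucose_g_mol: float | None
    volumetric: VolumetricRates
    specific: SpecificRates | None


class SulfurBudget(NamedTuple):
    """Sulfur inventory of the medium vs the cells, mmol/L."""

    s_yeast_extract: float
    s_thiosulfate: float
    s_cells: float

    @property
    def incorporation_ratio_pct(self) -> float:
        """Cellular sulfur over total medium sulfur, %."""
        total = self.s_yeast_extract + self.s_thiosulfate
        return 0.0 if self.s_cells == 0 else 100.0 * self.s_cells / total


class ThiosulfateYieldFit(NamedTuple):
    """OLS fit of maximum cell density on initial thiosulfate."""

    slope_mg_mmol: float
    intercept_mg_L: float
    slope_se: float
    x_intercept_mM: float  # extrapolated thiosulfate-equivalent of the intercept
    n_points: int


def od_to_dry_weight(od) -> float | np.ndarray:
    """Convert OD600 to cell dry weight, mg/L (330 mg/L per OD unit)."""
    arr = np.asarray(od, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("OD must be >= 0")
    out = arr * 330.0
    return float(out) if np.isscalar(od) else out


def log_mean(x1: float, x2: float) -> float:
    """Logarithmic mean (x2 - x1) / ln(x2/x1); equals x1 when x1 == x2."""
    if x1 <= 0 or x2 <= 0:
        raise InvalidInputError("log mean requires positive values")
    if np.isclose(x1, x2):
        return float(x1)
    return (x2 - x1) / np.log(x2 / x1)


def _co2_delta(run: FermentationRun, window, stoich: StoichiometryProfile) -> float:
    if run.co2_mode == "acetate_stoichiometric":
        return run.delta("acetate", window)
    return run.delta("co2", window)


def carbon_recovery(
    run: FermentationRun,
    window,
    mode: str = "C1",
    stoich: StoichiometryProfile = DEFAULT_STOICHIOMETRY,
) -> float:
    """Fraction of consumed-glucose carbon recovered in products, %.

    C1 counts cells (produced dry weight at 50 % carbon), lactate, acetate and
    CO2; C2 additionally counts L-alanine and EPS (glucose equivalents).  CO2
    follows the run's ``co2_mode``.
    """
    if mode not in ("C1", "C2"):
        raise InvalidInputError(f"mode must be 'C1' or 'C2', got {mode!r}")
    d_glu = run.delta("glucose_consumed", window)
    if d_glu <= 0:
        raise InvalidInputError("no glucose consumed over window: recovery undefined")
    ca = stoich.carbon_atoms
    cells_c = (
        stoich.cell_carbon_fraction * run.delta("cells", window) / ATOMIC_MASS["C"]
    )  # mg dw -> mmol C
    products_c = (
        cells_c
        + ca["lactate"] * run.delta("lactate", window)
        + ca["acetate"] * run.delta("acetate", window)
        + ca["co2"] * _co2_delta(run, window, stoich)
    )
    if mode == "C2":
        products_c += ca["alanine"] * run.delta("alanine", window)
        products_c += ca["eps_glucose_equiv"] * run.delta("eps_glucose_equiv", window)
    return 100.0 * products_c / (ca["glucose"] * d_glu)


def volumetric_rates(run: FermentationRun, window) -> VolumetricRates:
    """Volumetric rates over a window: cells (mg L-1 h-1), glucose and H2 (mmol L-1 h-1)."""
    a, b = run.resolve_window(window)
    dt = b - a
    return VolumetricRates(
        q_cells_mg_L_h=run.delta("cells", window) / dt,
        q_glucose_mM_h=run.delta("glucose_consumed", window) / dt,
        q_h2_mM_h=run.delta("h2", window) / dt,
    )


def specific_rates(run: FermentationRun, window) -> SpecificRates:
    """Specific glucose-consumption and H2-production rates, mmol g-1 h-1.

    The volumetric rate is divided by the logarithmic-mean biomass over the
    window (in g/L).  For exponential growth X(t) = X0 exp(mu t) with a truly
    constant specific rate q (production rate q X), the window estimate
    dP * mu / dX equals q exactly, and that is what dividing by the log-mean
    biomass computes — an arithmetic mean would bias q low over a growth
    phase.
    """
    a, b = run.resolve_window(window)
    x1, x2 = run.value_at("cells", a), run.value_at("cells", b)
    if x1 <= 0 or x2 <= 0:
        raise InvalidInputError("specific rates need positive biomass at both window ends")
    x_lm_g = log_mean(x1, x2) / 1000.0
    rates = volumetric_rates(run, window)
    return SpecificRates(
        q_glucose=rates.q_glucose_mM_h / x_lm_g,
        q_h2=rates.q_h2_mM_h / x_lm_g,
    )


def molar_yields(
    run: FermentationRun,
    window,
    cells_window=None,
) -> dict[str, float | None]:
    """Molar product yields on consumed glucose over a window.

    Returns mol/mol ratios (cells/glucose in g/mol, EPS in glucose-equivalent
    mol/mol) plus the H2/acetate ratio.  ``cells_window`` optionally computes
    the cell yield over a different window — batch reports conventionally
    state product yields cumulatively from inoculation but the cell yield over
    the growth phase, where cell production and glucose consumption are
    proportional.  Ratios whose numerator column is absent are ``None``.
    """
    d_glu = run.delta("glucose_consumed", window)
    if d_glu <= 0:
        raise InvalidInputError("no glucose consumed over window: yields undefined")

    def ratio(column: str) -> float | None:
        arr = getattr(run, column)
        if arr is None or not np.isfinite(arr).any():
            return None
        return run.delta(column, window) / d_glu

    d_acet = run.delta("acetate", window)
    d_h2 = ratio("h2")
    out: dict[str, float | None] = {
        "acetate_per_glucose": d_acet / d_glu,
        "lactate_per_glucose": ratio("lactate"),
        "h2_per_glucose": d_h2,
        "alanine_per_glucose": ratio("alanine"),
        "eps_per_glucose": ratio("eps_glucose_equiv"),
        "h2_per_acetate": (d_h2 * d_glu / d_acet) if d_acet > 0 and d_h2 is not None else None,
    }
    cw = window if cells_window is None else cells_window
    d_glu_c = run.delta("glucose_consumed", cw)
    out["cells_per_glucose_g_mol"] = (
        run.delta("cells", cw) / d_glu_c if d_glu_c > 0 else None
    )  # mg/mmol == g/mol
    return out


def yield_on_thiosulfate(
    points: Sequence[tuple[float, float]],
    limited_range_max_mM: float = 0.06,
) -> ThiosulfateYieldFit:
    """Cell yield on thiosulfate from maximum cell density vs initial thiosulfate.

    Ordinary least squares of maximum cell concentration (mg/L) on initial
    thiosulfate (mmol/L), restricted to the growth-limited range
    ``thiosulfate <= limited_range_max_mM``.  The slope is the yield Y_X/Thio
    in mg cells per mmol thiosulfate.  The x-axis intercept of the fitted
    line, ``-intercept/slope``, locates the thiosulfate-equivalent of the
    sulfur nutrients already present in the thiosulfate-free medium (the
    yeast extract): its magnitude is that equivalence in mmol/L.
    """
    pts = [(float(x), float(y)) for x, y in points if float(x) <= limited_range_max_mM]
    if len(pts) < 2:
        raise InvalidInputError(
            f"need >= 2 points with thiosulfate <= {limited_range_max_mM} mmol/L, got {len(pts)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise InvalidInputError("zero variance in thiosulfate: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    slope_se = float(model.bse[1]) if len(pts) > 2 else float("nan")
    return ThiosulfateYieldFit(
        slope_mg_mmol=float(slope),
        intercept_mg_L=float(intercept),
        slope_se=slope_se,
        x_intercept_mM=float(-intercept / slope),
        n_points=len(pts),
    )


def sulfur_budget(
    cells_mg_L: float,
    yeast_extract_g_L: float,
    thiosulfate_mM: float,
    stoich: StoichiometryProfile = DEFAULT_STOICHIOMETRY,
) -> SulfurBudget:
    """Sulfur inventory: medium sources vs what ended up in the cells.

    Yeast extract carries ~0.07 mmol organic sulfur (cystine + methionine) per
    gram; thiosulfate two sulfur atoms per mole; cellular sulfur follows from
    the elemental composition (S0.005 per C-mol of biomass).
    """
    if min(cells_mg_L, yeast_extract_g_L, thiosulfate_mM) < 0:
        raise InvalidInputError("sulfur-budget inputs must be >= 0")
    return SulfurBudget(
        s_yeast_extract=stoich.ye_sulfur_mmol_per_g * yeast_extract_g_L,
        s_thiosulfate=stoich.s_per_thiosulfate * thiosulfate_mM,
        s_cells=stoich.cell_sulfur_per_mg * cells_mg_L,
    )


def thiosulfate_detox_capacity(
    thiosulfate_mM: float, stoich: StoichiometryProfile = DEFAULT_STOICHIOMETRY
) -> float:
    """H2 oxidizable by reducing the given thiosulfate fully to sulfide, mmol/L.

    Four H2 are consumed per thiosulfate; comparing this capacity with the H2
    actually produced separates thiosulfate's detoxifying role (electron sink
    for H2) from its nutritional role (sulfur source).
    """
    if thiosulfate_mM < 0:
        raise InvalidInputError("thiosulfate must be >= 0")
    return stoich.h2_per_thiosulfate * thiosulfate_mM


def yield_report(
    run: FermentationRun,
    window,
    cells_window=None,
    stoich: StoichiometryProfile = DEFAULT_STOICHIOMETRY,
) -> YieldReport:
    """Assemble the full derived summary for one run and window."""
    a, b = run.resolve_window(window)
    yields = molar_yields(run, window, cells_window=cells_window)
    has_c2 = run.alanine is not None and run.eps_glucose_equiv is not None
    try:
        spec = specific_rates(run, window)
    except InvalidInputError:
        spec = None
    return YieldReport(
        window_h=(a, b),
        c1_recovery_pct=carbon_recovery(run, window, "C1", stoich),
        c2_recovery_pct=carbon_recovery(run, window, "C2", stoich) if has_c2 else None,
        volumetric=volumetric_rates(run, window),
        specific=spec,
        **{
            k: yields[k]
            for k in (
                "h2_per_acetate",
                "acetate_per_glucose",
                "lactate_per_glucose",
                "h2_per_glucose",
                "alanine_per_glucose",
                "eps_per_glucose",
                "cells_per_glucose_g_mol",
            )
        },
    )
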