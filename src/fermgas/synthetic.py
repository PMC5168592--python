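"""Synthetic batch fermentations with the structure the analysis assumes.

The generator emulates a sulfur-limited *T. maritima* batch culture: logistic
growth toward a biomass ceiling set by the available sulfur (initial
thiosulfate plus the thiosulfate-equivalent of the yeast extract's organic
sulfur), glucose consumption split between a growth-associated term and
maintenance, and products allocated by carbon fractions — the acetate pathway
(2 acetate + 2 CO2 per glucose, 2 H2 per acetate), lactate, L-alanine and EPS.
Because the carbon split is exhaustive (the cell fraction is the remainder),
noiseless runs close the full carbon balance exactly; with the alanine and EPS
branches switched off the C1 balance closes at 100 % and H2/acetate is exactly
2.  Sulfur limitation below a threshold shifts carbon from acetate to EPS,
reproducing the stress response seen in thiosulfate-starved cultures.

Gas production is routed through the headspace model under the closed-loop
5 % outlet-H2 controller, so the generated off-gas records exercise the full
forward/inverse chain.  Measurement noise is multiplicative Gaussian
(truncated at zero) on all measured channels; the noiseless truth is always
retained alongside.

This is deliberately not a mechanistic dual-substrate Monod model: the
analysis layer only needs the ceiling-versus-thiosulfate structure, realistic
magnitudes and exact stoichiometric closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .accounting import ATOMIC_MASS, FermentationRun, PhaseMarkers, StoichiometryProfile
from .exceptions import InvalidConfigError
from .gas_balance import (
    HeadspaceConfig,
    OutletGasSeries,
    ProductionSeries,
    closed_loop_n2_policy,
    simulate_headspace,
)

__all__ = ["SimulationConfig", "SyntheticRun", "simulate_run", "emit_fixture_tables"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic batch run.

    Defaults mirror the bioreactor study conditions: 60 mM glucose, 1 g/L
    yeast extract (equivalent to 0.03 mmol/L thiosulfate in sulfur terms), a
    cell yield on thiosulfate of 3617 mg/mmol, growth-phase specific rates in
    the 0.2-0.3 /h range, and 5 % relative measurement noise.

    ``f_acetate``/``f_lactate``/``f_alanine``/``f_eps`` are fractions of
    consumed-glucose carbon routed to each product pathway (the acetate
    fraction covers acetate plus its stoichiometric CO2); the remainder is
    cell carbon, so they must sum to < 1.
    """

    mu_max: float = 0.25  # 1/h
    yield_cells_per_thiosulfate: float = 3617.0  # mg cells per mmol thiosulfate
    ye_sulfur_equiv: float = 0.03  # mmol thiosulfate-equivalent per g yeast extract
    glucose_0: float = 60.0  # mmol/L
    thiosulfate_0: float = 0.06  # mmol/L
    yeast_extract: float = 1.0  # g/L
    initial_cells: float = 25.0  # mg/L (inoculum)
    f_acetate: float = 0.58
    f_lactate: float = 0.25
    f_alanine: float = 0.05
    f_eps: float = 0.06
    maintenance_glucose: float = 0.3  # mmol glucose per g cells per h
    eps_stress_boost: float = 0.20  # extra EPS carbon fraction at zero thiosulfate
    eps_stress_threshold: float = 0.06  # mmol/L below which the EPS shift engages
    noise_cv: float = 0.05
    seed: int = 0
    sample_interval: float = 0.25  # h
    t_end: float = 40.0  # h

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise InvalidConfigError("mu_max must be > 0")
        for name in (
            "yield_cells_per_thiosulfate",
            "glucose_0",
            "initial_cells",
            "sample_interval",
            "t_end",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("thiosulfate_0", "yeast_extract", "ye_sulfur_equiv", "noise_cv",
                     "maintenance_glucose", "eps_stress_boost"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        fr = self.product_fractions
        if any(f < 0 for f in fr.values()):
            raise InvalidConfigError("product fractions must be >= 0")
        if sum(fr.values()) >= 1.0:
            raise InvalidConfigError(
                "product carbon fractions must sum to < 1 (remainder is cell carbon); "
                f"got {sum(fr.values()):.3f}"
            )

    @property
    def product_fractions(self) -> dict[str, float]:
        """Effective product-carbon fractions after the sulfur-stress EPS shift."""
        f_eps = self.f_eps
        f_ac = self.f_acetate
        if self.eps_stress_threshold > 0:
            deficit = max(0.0, 1.0 - self.thiosulfate_0 / self.eps_stress_threshold)
            shift = self.eps_stress_boost * deficit
            f_eps += shift
            f_ac = max(f_ac - shift, 0.0)
        return {
            "acetate": f_ac,
            "lactate": self.f_lactate,
            "alanine": self.f_alanine,
            "eps": f_eps,
        }

    @property
    def biomass_ceiling(self) -> float:
        """Sulfur-set maximum cell density, mg/L."""
        s_equiv = self.thiosulfate_0 + self.ye_sulfur_equiv * self.yeast_extract
        return self.initial_cells + self.yield_cells_per_thiosulfate * s_equiv


@dataclass(frozen=True)
class SyntheticRun:
    """A generated run: noisy measurements plus the noiseless truth record."""

    run: FermentationRun
    truth_run: FermentationRun
    production: ProductionSeries | None
    outlet: OutletGasSeries | None
    config: SimulationConfig
    glucose_exhausted: bool
    truth: dict = field(default_factory=dict)

    @property
    def max_cells(self) -> float:
        """Maximum cell density estimate: the measured value at the growth-phase end.

        Reading the marker time rather than taking the maximum over all noisy
        samples keeps the estimator unbiased (the running maximum of a noisy
        plateau is biased high).
        """
        return self.run.value_at("cells", self.run.phases.t2)


# state vector indices: X, G, acetate, lactate, alanine, eps, h2, co2
_NSTATE = 8


def _rhs_factory(config: SimulationConfig, stoich: StoichiometryProfile):
    k = config.biomass_ceiling
    fr = config.product_fractions
    f_cell = 1.0 - sum(fr.values())
    w = sum(fr.values())
    g = {name: f / w for name, f in fr.items()}  # product-carbon split
    c_per_mg = stoich.cell_carbon_fraction / ATOMIC_MASS["C"]  # mmol C per mg cells

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        x = y[0]
        dx = config.mu_max * x * (1.0 - x / k)
        cell_c = c_per_mg * dx  # mmol C / L / h
        dg_growth = cell_c / (6.0 * f_cell)
        dg_maint = config.maintenance_glucose * x / 1000.0
        dg = dg_growth + dg_maint
        prod_c = 6.0 * dg - cell_c
        d_acet = g["acetate"] * prod_c / 3.0
        out = np.empty(_NSTATE)
        out[0] = dx
        out[1] = dg
        out[2] = d_acet
        out[3] = g["lactate"] * prod_c / 3.0
        out[4] = g["alanine"] * prod_c / 3.0
        out[5] = g["eps"] * prod_c / 6.0
        out[6] = stoich.h2_per_acetate * d_acet
        out[7] = d_acet  # 1 CO2 per acetate
        return out

    return rhs


def _phase_markers(time_h: np.ndarray, x: np.ndarray, ceiling: float) -> PhaseMarkers:
    x0 = x[0]
    above = np.nonzero(x >= x0 + 0.05 * (ceiling - x0))[0]
    t1 = float(time_h[above[0]]) if above.size else float(time_h[1])
    near = np.nonzero(x >= x0 + 0.98 * (ceiling - x0))[0]
    t2 = float(time_h[near[0]]) if near.size else float(time_h[-1])
    t3 = float(time_h[-1])
    if not t1 < t2:
        t1, t2 = float(time_h[0]), t3
    return PhaseMarkers(float(time_h[0]), t1, t2, t3)


def _noisy(rng: np.random.Generator, arr: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return arr.copy()
    out = arr * (1.0 + cv * rng.standard_normal(arr.shape))
    return np.clip(out, 0.0, None)


def simulate_run(
    config: SimulationConfig,
    headspace: HeadspaceConfig | None = None,
    stoich: StoichiometryProfile | None = None,
    include_gas: bool = True,
) -> SyntheticRun:
    """Generate one synthetic batch run (bit-reproducible for a fixed seed).

    Integrates the kinetic model to ``t_end``, stops product formation if
    glucose runs out (flagged), samples every ``sample_interval`` hours, and
    emits both noiseless truth and noisy measurement channels.  With
    ``include_gas`` the biological gas rates are pushed through the headspace
    model under the closed-loop setpoint controller to produce an off-gas
    record for the inverse problem.
    """
    if headspace is None:
        headspace = HeadspaceConfig()
    if stoich is None:
        stoich = StoichiometryProfile()
    rng = np.random.default_rng(config.seed)
    rhs = _rhs_factory(config, stoich)

    def glucose_gone(_t, y):
        return config.glucose_0 - y[1]

    glucose_gone.terminal = True
    glucose_gone.direction = -1

    t = np.arange(0.0, config.t_end + 1e-9, config.sample_interval)
    y0 = np.zeros(_NSTATE)
    y0[0] = config.initial_cells
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        y0,
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        events=glucose_gone,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"kinetic integration failed: {sol.message}")
    exhausted = sol.status == 1  # glucose-exhaustion event fired
    y = sol.y
    if exhausted:
        # hold state flat after exhaustion (fermentation stops, cells persist)
        n = sol.t.size
        pad = t.size - n
        y = np.hstack([y, np.repeat(y[:, -1:], pad, axis=1)])

    x, g_cons, acet, lac, ala, eps, h2, co2 = y
    phases = _phase_markers(t, x, config.biomass_ceiling)

    def make_run(noise_cv: float) -> FermentationRun:
        return FermentationRun(
            time_h=t,
            cells=_noisy(rng, x, noise_cv),
            glucose_consumed=np.maximum.accumulate(_noisy(rng, g_cons, noise_cv)),
            lactate=_noisy(rng, lac, noise_cv),
            acetate=_noisy(rng, acet, noise_cv),
            alanine=_noisy(rng, ala, noise_cv),
            eps_glucose_equiv=_noisy(rng, eps, noise_cv),
            h2=_noisy(rng, h2, noise_cv),
            co2=_noisy(rng, co2, noise_cv),
            thiosulfate_initial_mM=config.thiosulfate_0,
            yeast_extract_g_L=config.yeast_extract,
            phases=phases,
            co2_mode="measured",
            label=f"synthetic (seed {config.seed})",
        )

    truth_run = make_run(0.0)
    run = make_run(config.noise_cv)

    production = None
    outlet = None
    if include_gas:
        # instantaneous molar rates from the model RHS, converted to
        # volumetric flows at headspace temperature (mL/min)
        rates = np.array([rhs(ti, y[:, i]) for i, ti in enumerate(t)]).T
        if exhausted:
            stopped = t > sol.t[-1]
            rates[:, stopped] = 0.0
        ml_per_mmol = 1.0 / headspace.mmol_per_mL_gas
        to_flow = headspace.liquid_volume_L * ml_per_mmol / 60.0
        production = ProductionSeries(
            time_h=t,
            q_h2=np.clip(rates[6] * to_flow, 0.0, None),
            q_co2=np.clip(rates[7] * to_flow, 0.0, None),
        )
        policy = closed_loop_n2_policy(production, headspace)
        outlet = simulate_headspace(production, policy, headspace)
        if config.noise_cv > 0:
            fr = np.vstack(
                [
                    _noisy(rng, outlet.p_n2, config.noise_cv),
                    _noisy(rng, outlet.p_h2, config.noise_cv),
                    _noisy(rng, outlet.p_co2, config.noise_cv),
                ]
            )
            fr *= 100.0 / fr.sum(axis=0)  # renormalize so the record stays consistent
            outlet = OutletGasSeries(
                time_h=outlet.time_h,
                p_n2=fr[0],
                p_h2=fr[1],
                p_co2=fr[2],
                q_n2_ref=_noisy(rng, outlet.q_n2_ref, config.noise_cv),
                sum_tolerance_pct=0.01,
            )

    return SyntheticRun(
        run=run,
        truth_run=truth_run,
        production=production,
        outlet=outlet,
        config=config,
        glucose_exhausted=bool(exhausted),
        truth={
            "biomass_ceiling_mg_L": config.biomass_ceiling,
            "yield_cells_per_thiosulfate": config.yield_cells_per_thiosulfate,
            "product_fractions": config.product_fractions,
            "mu_max": config.mu_max,
        },
    )


def emit_fixture_tables(outdir: str | Path) -> list[Path]:
    """Write the packaged reference datasets as run-schema CSV files.

    One file per batch condition (serum-bottle nutriment screen and the two
    bioreactor series), in the same CSV schema :func:`fermgas.io.load_run`
    reads, so the reference data flow through exactly the same path as
    user-supplied runs.
    """
    from . import datasets
    from .io import write_run

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cond in ("control", "DMSO", "sulfur", "methionine", "thiosulfate", "cysteine", "sulfide"):
        p = outdir / f"serum_bottle_{cond}.csv"
        write_run(datasets.serum_bottle_run(cond), p)
        paths.append(p)
    for ph2 in (7.1, 71.4, 178.5, 606.9):
        p = outdir / f"ph2_{str(ph2).replace('.', 'p')}_mbar.csv"
        write_run(datasets.ph2_run(ph2), p)
        paths.append(p)
    for thio in datasets.thiosulfate_concentrations():
        p = outdir / f"thiosulfate_{str(thio).replace('.', 'p')}_mM.csv"
        write_run(datasets.thiosulfate_run(thio), p)
        paths.append(p)
    return paths
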