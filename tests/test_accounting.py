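import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermgas import datasets
from fermgas.accounting import (
    FermentationRun,
    PhaseMarkers,
    StoichiometryProfile,
    carbon_recovery,
    log_mean,
    molar_yields,
    od_to_dry_weight,
    specific_rates,
    sulfur_budget,
    thiosulfate_detox_capacity,
    volumetric_rates,
    yield_on_thiosulfate,
    yield_report,
)
from fermgas.exceptions import InvalidInputError


def balanced_run() -> FermentationRun:
    """Perfect-stoichiometry run: glucose -> 2 acetate + 2 CO2 + 4 H2 plus
    cells carrying exactly the remaining carbon."""
    t = np.array([0.0, 10.0, 20.0])
    glu = np.array([0.0, 5.0, 10.0])
    acet_frac = 0.9  # fraction of glucose carbon down the acetate pathway
    acet = glu * 6 * acet_frac / 3
    cells_c = glu * 6 * (1 - acet_frac)  # mmol C
    cells = 100.0 + cells_c * 12.011 / 0.5  # mg dw with 50 % carbon
    return FermentationRun(
        time_h=t,
        cells=cells,
        glucose_consumed=glu,
        lactate=np.zeros(3),
        acetate=acet,
        h2=2 * acet,
        co2=acet.copy(),
        co2_mode="measured",
        phases=PhaseMarkers(0.0, 0.0, 20.0, 20.0),
    )


class TestOdConversion:
    @pytest.mark.parametrize("od, mg", [(1.0, 330.0), (0.0, 0.0), (0.5, 165.0)])
    def test_linear_calibration(self, od, mg):
        assert od_to_dry_weight(od) == pytest.approx(mg)

    def test_negative_od_rejected(self):
        with pytest.raises(InvalidInputError):
            od_to_dry_weight(-0.1)


class TestCarbonRecovery:
    def test_serum_bottle_control_growth_phase(self):
        """Control culture at 14.5 h: ~96.5 % of consumed-glucose carbon
        recovered in cells, lactate, acetate and stoichiometric CO2."""
        run = datasets.serum_bottle_run("control")
        assert carbon_recovery(run, (0.0, 14.5), "C1") == pytest.approx(96.5, abs=0.1)

    def test_bioreactor_c2_recovery_with_measured_co2(self):
        run = datasets.thiosulfate_run(0.24)
        assert carbon_recovery(run, "to_t2", "C2") == pytest.approx(95.8, abs=0.1)

    def test_perfect_stoichiometry_closes_at_100(self):
        assert carbon_recovery(balanced_run(), (0.0, 20.0), "C1") == pytest.approx(100.0)

    def test_c2_at_least_c1(self):
        run = datasets.thiosulfate_run(0.0)
        c1 = carbon_recovery(run, "to_t2", "C1")
        c2 = carbon_recovery(run, "to_t2", "C2")
        assert c2 >= c1
        assert c1 == pytest.approx(54.9, abs=0.2)

    def test_zero_glucose_signalled(self):
        # the 0.03 mM run consumed no glucose before growth onset (t0 -> t1)
        run = datasets.thiosulfate_run(0.03)
        with pytest.raises(InvalidInputError):
            carbon_recovery(run, (0.0, run.phases.t1))


class TestRates:
    def test_serum_bottle_control_productivities(self):
        run = datasets.serum_bottle_run("control")
        rates = volumetric_rates(run, (0.0, 14.5))
        assert rates.q_cells_mg_L_h == pytest.approx(7.13, abs=0.01)
        assert rates.q_glucose_mM_h == pytest.approx(0.26, abs=0.005)
        assert rates.q_h2_mM_h == pytest.approx(0.64, abs=0.005)

    def test_growth_phase_cell_productivity(self):
        rates = volumetric_rates(datasets.thiosulfate_run(0.12), "growth")
        assert rates.q_cells_mg_L_h == pytest.approx(24.8, abs=0.1)

    def test_no_change_gives_zero(self):
        run = balanced_run()
        flat = FermentationRun(
            time_h=run.time_h,
            cells=np.full(3, 50.0),
            glucose_consumed=np.full(3, 5.0),
            lactate=np.zeros(3),
            acetate=np.full(3, 1.0),
            h2=np.full(3, 2.0),
            co2=np.full(3, 1.0),
        )
        rates = volumetric_rates(flat, (0.0, 20.0))
        assert rates == (0.0, 0.0, 0.0)

    def test_specific_h2_rate_with_log_mean_biomass(self):
        """The growth-phase q_H2 of the thiosulfate-free run comes out at
        13.4 mmol/g/h only with logarithmic-mean biomass averaging."""
        spec = specific_rates(datasets.thiosulfate_run(0.0), "growth")
        assert spec.q_h2 == pytest.approx(13.4, abs=0.1)
        assert spec.q_glucose == pytest.approx(8.9, abs=0.1)

    def test_constant_biomass_limit(self):
        run = balanced_run()
        const = FermentationRun(
            time_h=run.time_h,
            cells=np.full(3, 200.0),
            glucose_consumed=np.array([0.0, 5.0, 10.0]),
            lactate=np.zeros(3),
            acetate=np.zeros(3),
            h2=np.array([0.0, 10.0, 20.0]),
            co2=np.zeros(3),
        )
        spec = specific_rates(const, (0.0, 20.0))
        assert spec.q_h2 == pytest.approx((20.0 / 20.0) / 0.2)

    def test_exponential_growth_recovers_constant_q_exactly(self):
        """For X = X0 e^(mu t) and production rate q X, the log-mean estimator
        returns q exactly, whatever the window."""
        mu, q, x0 = 0.3, 5.0, 20.0
        t = np.linspace(0.0, 10.0, 50)
        x = x0 * np.exp(mu * t)
        prod = q * (x - x0) / mu / 1000.0  # integral of q X dt, X in g/L
        run = FermentationRun(
            time_h=t,
            cells=x,
            glucose_consumed=prod.copy(),
            lactate=np.zeros_like(t),
            acetate=np.zeros_like(t),
            h2=prod.copy(),
            co2=np.zeros_like(t),
        )
        spec = specific_rates(run, (t[3], t[40]))
        assert spec.q_h2 == pytest.approx(q, rel=1e-9)

    def test_volumetric_equals_specific_times_log_mean(self):
        run = datasets.thiosulfate_run(0.06)
        a, b = run.resolve_window("growth")
        x_lm = log_mean(run.value_at("cells", a), run.value_at("cells", b)) / 1000.0
        assert volumetric_rates(run, "growth").q_h2_mM_h == pytest.approx(
            specific_rates(run, "growth").q_h2 * x_lm
        )

    def test_zero_biomass_signalled(self):
        run = balanced_run()
        zeroed = FermentationRun(
            time_h=run.time_h,
            cells=np.array([0.0, 10.0, 20.0]),
            glucose_consumed=run.glucose_consumed,
            lactate=run.lactate,
            acetate=run.acetate,
            h2=run.h2,
            co2=run.co2,
        )
        with pytest.raises(InvalidInputError):
            specific_rates(zeroed, (0.0, 20.0))


class TestMolarYields:
    def test_serum_bottle_h2_per_acetate(self):
        run = datasets.serum_bottle_run("control")
        y = molar_yields(run, (0.0, 14.5))
        assert y["h2_per_acetate"] == pytest.approx(1.71, abs=0.02)

    def test_lactate_shift_at_high_hydrogen_pressure(self):
        """At 607 mbar imposed H2 the lactate yield rises to ~0.8 mol/mol."""
        run = datasets.ph2_run(606.9)
        y = molar_yields(run, "total")
        assert y["lactate_per_glucose"] == pytest.approx(0.82, abs=0.01)
        low = molar_yields(datasets.ph2_run(7.1), "total")
        assert low["lactate_per_glucose"] == pytest.approx(0.5, abs=0.05)

    def test_cell_yield_uses_growth_window(self):
        run = datasets.thiosulfate_run(0.01)
        y = molar_yields(run, "to_t2", cells_window="growth")
        assert y["cells_per_glucose_g_mol"] == pytest.approx(8.7, abs=0.1)

    def test_zero_products_give_zero_ratios(self):
        run = balanced_run()
        y = molar_yields(
            FermentationRun(
                time_h=run.time_h,
                cells=run.cells,
                glucose_consumed=run.glucose_consumed,
                lactate=np.zeros(3),
                acetate=np.zeros(3),
                h2=np.zeros(3),
                co2=np.zeros(3),
            ),
            (0.0, 20.0),
        )
        assert y["acetate_per_glucose"] == 0.0
        assert y["h2_per_acetate"] is None


class TestThiosulfateYield:
    def test_limited_range_regression_on_reference_points(self):
        fit = yield_on_thiosulfate(datasets.thiosulfate_yield_points())
        assert fit.n_points == 4
        assert fit.slope_mg_mmol == pytest.approx(3732.1, abs=0.5)
        assert abs(fit.slope_mg_mmol - 3617.0) <= 176.0
        # extrapolated x-intercept locates the yeast-extract sulfur equivalence
        assert -fit.x_intercept_mM == pytest.approx(0.037, abs=0.005)

    def test_two_point_line(self):
        fit = yield_on_thiosulfate([(0.0, 0.0), (0.05, 0.05)])
        assert fit.slope_mg_mmol == pytest.approx(1.0)
        assert fit.intercept_mg_L == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_from_noisy_points(self):
        """2-SE coverage of the OLS slope: across replicate noisy designs
        (sigma = 10 mg/L, n = 12, known slope 3000) at least ~95 % of fits
        bracket the true slope."""
        rng = np.random.default_rng(42)
        slope, n = 3000.0, 12
        x = np.tile([0.0, 0.01, 0.03, 0.06], 3)[:n]
        hits = 0
        for _ in range(50):
            y = 120.0 + slope * x + rng.normal(0.0, 10.0, n)
            fit = yield_on_thiosulfate(list(zip(x, y)))
            hits += abs(fit.slope_mg_mmol - slope) <= 2 * fit.slope_se
        assert hits >= 45

    def test_scale_equivariance(self):
        pts = datasets.thiosulfate_yield_points()
        fit = yield_on_thiosulfate(pts)
        scaled = yield_on_thiosulfate([(x, 3.0 * y) for x, y in pts])
        assert scaled.slope_mg_mmol == pytest.approx(3.0 * fit.slope_mg_mmol)

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(InvalidInputError):
            yield_on_thiosulfate([(0.0, 1.0)])
        with pytest.raises(InvalidInputError):
            yield_on_thiosulfate([(0.02, 1.0), (0.02, 2.0)])
        with pytest.raises(InvalidInputError):
            yield_on_thiosulfate([(0.5, 1.0), (0.9, 2.0)])  # all outside range


class TestSulfurBudget:
    @pytest.mark.parametrize(
        "cells, ye, thio, s_cells, ratio",
        [(128.0, 1.0, 0.0, 0.025, 35), (354.0, 1.0, 0.06, 0.068, 36)],
    )
    def test_reference_conditions(self, cells, ye, thio, s_cells, ratio):
        b = sulfur_budget(cells, ye, thio)
        assert b.s_cells == pytest.approx(s_cells, abs=0.001)
        assert round(b.incorporation_ratio_pct) == ratio

    def test_zero_cells(self):
        b = sulfur_budget(0.0, 1.0, 0.1)
        assert b.s_cells == 0.0
        assert b.incorporation_ratio_pct == 0.0

    def test_formula_unit_mass(self):
        assert StoichiometryProfile().cell_formula_mass == pytest.approx(26.18, abs=0.02)


class TestDetoxCapacity:
    @pytest.mark.parametrize("thio, h2", [(0.15, 0.6), (0.0, 0.0), (1.0, 4.0)])
    def test_four_h2_per_thiosulfate(self, thio, h2):
        assert thiosulfate_detox_capacity(thio) == pytest.approx(h2)

    def test_capacity_small_against_actual_production(self):
        """0.15 mmol/L thiosulfate can only sink 0.6 of the ~47 mmol/L H2 the
        corresponding serum-bottle culture produced: the growth stimulation
        cannot be a detoxification effect."""
        produced = datasets.serum_bottle_run("thiosulfate").h2[-1]
        assert thiosulfate_detox_capacity(0.15) / produced < 0.02


class TestYieldReport:
    def test_full_report_assembles(self):
        run = datasets.thiosulfate_run(0.12)
        rep = yield_report(run, "to_t2", cells_window="growth")
        assert rep.c1_recovery_pct == pytest.approx(79.2, abs=0.3)
        assert rep.c2_recovery_pct == pytest.approx(92.2, abs=0.3)
        assert rep.cells_per_glucose_g_mol == pytest.approx(8.9, abs=0.1)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    window=st.tuples(st.floats(0.0, 9.0), st.floats(10.0, 20.0)),
    acet_frac=st.floats(0.3, 0.95),
)
def test_recovery_invariant_under_window_and_split(window, acet_frac):
    """Any run built with exact stoichiometric closure reports 100 % C1
    recovery and H2/acetate = 2 on any window with glucose consumption."""
    t = np.array([0.0, 10.0, 20.0])
    glu = np.array([0.0, 5.0, 10.0])
    acet = glu * 6 * acet_frac / 3
    cells = 100.0 + glu * 6 * (1 - acet_frac) * 12.011 / 0.5
    run = FermentationRun(
        time_h=t,
        cells=cells,
        glucose_consumed=glu,
        lactate=np.zeros(3),
        acetate=acet,
        h2=2 * acet,
        co2=acet.copy(),
        co2_mode="measured",
    )
    assert carbon_recovery(run, window, "C1") == pytest.approx(100.0)
    assert molar_yields(run, window)["h2_per_acetate"] == pytest.approx(2.0)
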