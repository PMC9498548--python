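"""CKD stage-ladder model: bias arithmetic, structure, conservation, monotonicity."""

import numpy as np
import pytest

from ckdflow.ckd import (
    COUNTER_STOCKS,
    STAGES,
    STATE_STOCKS,
    build_ckd_model,
    counter_for_stage,
    default_parameters,
    endpoint,
    total_bias,
    unmonitored_fraction,
)
from ckdflow.engine import BOUNDARY, SimulationConfig, simulate, validate_model


class TestDefaults:
    def test_population_is_the_2020_tennessee_census(self, params):
        assert params.population_init == 6_910_840

    def test_base_risk_rates(self, params):
        assert params.diabetes_rate == 0.80
        assert params.hypertension_rate == 0.80

    def test_per_stage_provider_bias_base_values(self, params):
        expected = {"1": 0.8, "2": 0.08, "3": 0.16, "4": 0.073, "5": 0.152,
                    "esrd": 0.33}
        for stage, value in expected.items():
            assert getattr(params, f"provider_bias_{stage}") == value

    def test_percentage_rates_are_stored_to_two_decimals(self, params):
        assert params.replace(diabetes_rate=0.804).diabetes_rate == 0.80
        # bias levels are dimensionless and keep their printed precision
        assert params.provider_bias_4 == 0.073

    def test_negative_rate_is_rejected_naming_the_field(self, params):
        with pytest.raises(ValueError, match="diet_rate"):
            params.replace(diet_rate=-1.0)

    def test_fractions_must_stay_in_unit_interval(self, params):
        with pytest.raises(ValueError, match="screening_coverage"):
            params.replace(screening_coverage=1.5)

    def test_unknown_override_is_rejected(self, params):
        with pytest.raises(KeyError, match="no_such_rate"):
            params.replace(no_such_rate=1.0)


class TestTotalBias:
    def test_sum_of_four_components(self, params):
        p = params.replace(
            patient_bias_2=0.2, provider_bias_2=0.2,
            nephrologist_bias_2=0.2, system_bias_2=0.2,
        )
        assert total_bias("2", p) == pytest.approx(0.8)

    def test_zero_components_give_zero(self, params):
        p = params.replace(
            patient_bias_3=0, provider_bias_3=0,
            nephrologist_bias_3=0, system_bias_3=0,
        )
        assert total_bias("3", p) == 0.0

    def test_raising_one_component_raises_total_by_the_same_amount(self, params):
        before = total_bias("1", params)
        p = params.replace(provider_bias_1=params.provider_bias_1 + 0.5)
        assert total_bias("1", p) == pytest.approx(before + 0.5)

    def test_unknown_stage_is_an_error(self, params):
        with pytest.raises(KeyError, match="stage"):
            total_bias("6", params)


class TestUnmonitoredFraction:
    def test_zero_bias_gives_zero(self, params):
        assert unmonitored_fraction(0.0, params) == 0.0

    def test_clamped_at_one(self, params):
        p = params.replace(bias_to_unmonitored_gain=0.5, screening_coverage=0.0)
        assert unmonitored_fraction(3.0, p) == 1.0

    def test_linear_below_the_clamp(self, params):
        p = params.replace(bias_to_unmonitored_gain=0.5, screening_coverage=0.0)
        assert unmonitored_fraction(0.8, p) == pytest.approx(0.4)

    def test_screening_shrinks_the_unmonitored_pool(self, params):
        open_loop = params.replace(screening_coverage=0.0)
        screened = params.replace(screening_coverage=0.6)
        assert unmonitored_fraction(1.0, screened) < unmonitored_fraction(1.0, open_loop)

    def test_monotone_in_bias(self, params):
        values = [unmonitored_fraction(b, params) for b in np.linspace(0, 4, 25)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_negative_bias_is_rejected(self, params):
        with pytest.raises(ValueError):
            unmonitored_fraction(-0.1, params)


class TestModelStructure:
    def test_stock_and_flow_census(self, params):
        spec = build_ckd_model(params)
        stocks = spec.stock_names()
        assert len(stocks) == 16
        assert set(STATE_STOCKS) | set(COUNTER_STOCKS) == set(stocks)
        real = [f for f in spec.flows if f.mirrors is None]
        assert sum(f.name == "incidence" for f in real) == 1
        assert sum(f.name.startswith("progress_") for f in real) == 5
        assert sum(f.source == "ESRD" for f in real) == 3
        assert validate_model(spec).ok

    def test_all_stocks_start_at_zero_except_population(self, params):
        spec = build_ckd_model(params)
        for stock in spec.stocks:
            expected = params.population_init if stock.name == "Population" else 0.0
            assert stock.initial_value == expected

    def test_counters_mirror_their_ladder_flows(self, params):
        spec = build_ckd_model(params)
        mirrors = {f.sink: f.mirrors for f in spec.flows if f.mirrors is not None}
        assert mirrors["ProgressionTo2"] == "progress_1"
        assert mirrors["ProgressionToESRD"] == "progress_5"
        assert mirrors["DeathIncidence"] == "esrd_death"
        assert all(
            f.source == BOUNDARY for f in spec.flows if f.mirrors is not None
        )

    def test_full_monitoring_slowdown_removes_bias_dependence(self, params, config):
        # rho = 1: monitored and unmonitored progress identically
        base = params.replace(monitored_slowdown=1.0)
        raised = base.replace(provider_bias_1=2.5)
        t_base = simulate(build_ckd_model(base), config)
        t_raised = simulate(build_ckd_model(raised), config)
        np.testing.assert_array_equal(
            t_base.series["progress_1"], t_raised.series["progress_1"]
        )

    def test_zero_bias_and_zero_slowdown_freeze_the_ladder(self, params, config):
        zeros = {
            f"{comp}_{stage}": 0.0
            for stage in STAGES
            for comp in ("patient_bias", "provider_bias",
                         "nephrologist_bias", "system_bias")
        }
        frozen = params.replace(monitored_slowdown=0.0, **zeros)
        traj = simulate(build_ckd_model(frozen), config)
        for k in range(1, 6):
            assert np.all(traj.series[f"progress_{k}"] == 0.0)
        assert traj.series["Stage1"][-1] > 0  # incidence still accumulates
        assert np.all(traj.series["Stage2"] == 0.0)


class TestBaseRunInvariants:
    def test_population_mass_is_conserved(self, params, base_run):
        total = np.sum([base_run.series[s] for s in STATE_STOCKS], axis=0)
        np.testing.assert_allclose(total, params.population_init, rtol=1e-9)

    def test_counters_are_non_decreasing(self, base_run):
        for counter in COUNTER_STOCKS:
            assert np.all(np.diff(base_run.series[counter]) >= -1e-12), counter

    def test_downstream_counters_never_exceed_upstream(self, base_run):
        chain = ["ProgressionTo2", "ProgressionTo3", "ProgressionTo4",
                 "ProgressionTo5", "ProgressionToESRD"]
        for upstream, downstream in zip(chain, chain[1:]):
            assert np.all(
                base_run.series[downstream] <= base_run.series[upstream] + 1e-9
            ), (upstream, downstream)

    def test_every_stage_sees_flow_by_the_final_year(self, base_run):
        for counter in COUNTER_STOCKS:
            assert base_run.series[counter][-1] > 0.0, counter


class TestBiasMonotonicity:
    @pytest.mark.parametrize("stage", ["1", "3", "esrd"])
    @pytest.mark.parametrize("component", ["patient_bias", "system_bias"])
    def test_raising_a_component_weakly_raises_downstream_progression(
        self, params, config, stage, component, base_run
    ):
        counter = counter_for_stage(stage)
        field = f"{component}_{stage}"
        raised = params.replace(**{field: getattr(params, field) + 0.6})
        traj = simulate(build_ckd_model(raised), config)
        assert np.all(
            traj.series[counter] >= base_run.series[counter] - 1e-9
        ), field


class TestEndpoint:
    def test_counters_are_zero_at_the_start_year(self, base_run):
        for counter in COUNTER_STOCKS:
            assert endpoint(base_run, counter, 2010.0) == 0.0

    def test_constant_series_is_constant_at_any_grid_year(self, params):
        frozen = params.replace(
            diabetes_rate=0, hypertension_rate=0, diet_rate=0, lifestyle_rate=0
        )
        traj = simulate(build_ckd_model(frozen), SimulationConfig(2010, 2022, 0.25))
        for year in (2010.0, 2015.5, 2022.0):
            assert endpoint(traj, "Population", year) == params.population_init

    def test_off_grid_year_and_unknown_series_error(self, base_run):
        with pytest.raises(ValueError, match="grid"):
            endpoint(base_run, "Population", 2010.01)
        with pytest.raises(KeyError, match="NoSuchSeries"):
            endpoint(base_run, "NoSuchSeries", 2010.0)
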